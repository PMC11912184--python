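"""DeepLIFT rescale-rule attribution for every node in every layer.

Contributions are propagated from a target (by default the pre-sigmoid logit
of the compound-layer head) back through the effective, masked weights.
Linear pieces keep their weights as multipliers; each tanh (and, when the
target is the probability, the output sigmoid) contributes the rescale
multiplier

    m = (f(z) - f(z0)) / (z - z0),

falling back to f'(z0) when |z - z0| < 1e-7. A node's sample-level score is
its multiplier-to-target times its activation difference from the reference,
and per layer these scores sum exactly to the target difference t - t0
(the completeness identity). Aggregate importance over a cohort is
C = (1/N) |sum_s C_s| — the absolute value of the signed mean, so opposing
sample-level contributions cancel; a mean-of-absolute variant is available
behind a flag and is not the published formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import Activations, ModelParams, OmicsTensor, _sigmoid, forward

__all__ = [
    "AttributionReport",
    "reference_forward",
    "deeplift_sample",
    "attribute",
    "aggregate_importance",
    "rank_nodes",
    "edge_flow_scores",
]

RESCALE_FALLBACK = 1e-7
LAYERS = ("gene", "pathway", "compound")


def _as_values(x) -> np.ndarray:
    values = x.values if isinstance(x, OmicsTensor) else np.asarray(x, dtype=float)
    if values.ndim == 2:
        values = values[None, :, :]
    return values


def _rescale(delta_a: np.ndarray, delta_z: np.ndarray, deriv_at_ref: np.ndarray) -> np.ndarray:
    """Elementwise (f(z)-f(z0))/(z-z0) with the derivative fallback near 0."""
    small = np.abs(delta_z) < RESCALE_FALLBACK
    safe = np.where(small, 1.0, delta_z)
    return np.where(small, deriv_at_ref, delta_a / safe)


def reference_forward(params: ModelParams, x0: np.ndarray, target: str = "logit"
                      ) -> tuple[Activations, float]:
    """Forward pass on the reference input; returns activations and t0."""
    acts = forward(_as_values(x0), params)
    t0 = acts.logit3[0] if target == "logit" else acts.p3[0]
    return acts, float(t0)


def _multipliers(params: ModelParams, acts: Activations, ref: Activations,
                 target: str):
    """Rescale multipliers from each layer's nodes to the target, batched."""
    if params.activation == "tanh":
        d1, d2, d3 = (1 - ref.h1 ** 2, 1 - ref.h2 ** 2, 1 - ref.h3 ** 2)
    else:
        d1 = d2 = d3 = None  # identity: derivative 1
    ones = np.ones_like
    r1 = _rescale(acts.h1 - ref.h1, acts.z1 - ref.z1, d1 if d1 is not None else ones(acts.z1))
    r2 = _rescale(acts.h2 - ref.h2, acts.z2 - ref.z2, d2 if d2 is not None else ones(acts.z2))
    r3 = _rescale(acts.h3 - ref.h3, acts.z3 - ref.z3, d3 if d3 is not None else ones(acts.z3))

    if target == "probability":
        dp = acts.p3 - ref.p3
        dz = acts.logit3 - ref.logit3
        deriv = ref.p3 * (1 - ref.p3)
        r_out = _rescale(dp, dz, np.broadcast_to(deriv, dp.shape))
        m_h3 = r_out[:, None] * params.head_out_w[None, :]
    elif target == "logit":
        m_h3 = np.broadcast_to(params.head_out_w, acts.h3.shape).copy()
    else:
        raise ValueError("target must be 'logit' or 'probability'")
    m_h2 = (r3 * m_h3) @ params.effective_w_pc().T
    m_h1 = (r2 * m_h2) @ params.effective_w_gp().T
    m_x = params.w_gene[None, :, :] * (r1 * m_h1)[:, :, None]
    return m_h1, m_h2, m_h3, m_x


def deeplift_batch(
    params: ModelParams,
    x,
    x0: np.ndarray | None = None,
    target: str = "logit",
) -> dict:
    """Sample-level contributions of every node for a batch of samples.

    Returns a dict with per-layer N x n_l contribution matrices (plus the
    N x G x 4 input-channel contributions), the target differences ``delta_t``
    and per-layer completeness residuals.
    """
    values = _as_values(x)
    for name in ("w_gene", "w_gp", "w_pc"):
        if not np.isfinite(getattr(params, name)).all():
            raise ValueError(f"parameters contain non-finite values ({name}); "
                             "attribution requires a trained, finite model")
    if x0 is None:
        x0 = np.zeros(values.shape[1:])
    x0 = np.asarray(x0, dtype=float)
    ref, t0 = reference_forward(params, x0, target)
    acts = forward(values, params)
    t = acts.logit3 if target == "logit" else acts.p3

    m_h1, m_h2, m_h3, m_x = _multipliers(params, acts, ref, target)
    contribs = {
        "gene": m_h1 * (acts.h1 - ref.h1),
        "pathway": m_h2 * (acts.h2 - ref.h2),
        "compound": m_h3 * (acts.h3 - ref.h3),
        "input": m_x * (values - x0[None, :, :]),
    }
    delta_t = t - t0
    residuals = {
        layer: np.abs(contribs[layer].sum(axis=1) - delta_t) for layer in LAYERS
    }
    return {"contribs": contribs, "delta_t": delta_t, "residuals": residuals,
            "t": t, "t0": t0}


def deeplift_sample(
    params: ModelParams,
    x: np.ndarray,
    x0: np.ndarray | None = None,
    target: str = "logit",
) -> dict[str, np.ndarray]:
    """Per-layer contribution vectors for a single sample."""
    out = deeplift_batch(params, np.asarray(x, dtype=float)[None, ...], x0, target)
    result = {layer: out["contribs"][layer][0] for layer in LAYERS}
    result["input"] = out["contribs"]["input"][0]
    return result


def aggregate_importance(contribs: np.ndarray, mean_absolute: bool = False) -> np.ndarray:
    """Cohort importance C = (1/N)|sum_s C_s| per node.

    ``mean_absolute=True`` switches to (1/N) sum_s |C_s|, which does not
    cancel opposing signs; it is an off-formula diagnostic, not the default.
    """
    contribs = np.asarray(contribs, dtype=float)
    if contribs.shape[0] < 1:
        raise ValueError("need at least one sample")
    if mean_absolute:
        return np.abs(contribs).mean(axis=0)
    return np.abs(contribs.sum(axis=0)) / contribs.shape[0]


def rank_nodes(
    importance: Sequence[float], node_ids: Sequence[str], k: int,
) -> list[tuple[str, float]]:
    """Top-k nodes by importance, descending; ties broken by node id."""
    importance = np.asarray(importance, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(importance):
        raise ValueError(f"k={k} exceeds layer size {len(importance)}")
    order = sorted(range(len(importance)), key=lambda i: (-importance[i], node_ids[i]))
    return [(node_ids[i], float(importance[i])) for i in order[:k]]


@dataclass
class AttributionReport:
    """Contributions, aggregate importance, rankings and completeness checks."""

    per_layer_contribs: dict[str, np.ndarray]
    importance: dict[str, np.ndarray]
    rankings: dict[str, list[tuple[str, float]]]
    completeness_residuals: dict[str, np.ndarray]
    node_names: dict[str, list[str]]
    reference_description: str
    target: str
    delta_t: np.ndarray

    def max_residual(self) -> float:
        return float(max(r.max() for r in self.completeness_residuals.values()))

    def top_k(self, layer: str, k: int) -> list[tuple[str, float]]:
        return rank_nodes(self.importance[layer], self.node_names[layer], k)

    def to_json_dict(self) -> dict:
        return {
            "reference": self.reference_description,
            "target": self.target,
            "n_samples": int(self.delta_t.shape[0]),
            "max_completeness_residual": self.max_residual(),
            "layers": {
                layer: {
                    "node_ids": self.node_names[layer],
                    "importance": [float(v) for v in self.importance[layer]],
                    "ranking": [{"node": n, "importance": s}
                                for n, s in self.rankings[layer]],
                }
                for layer in LAYERS
            },
        }

    def write(self, outdir: str | Path) -> list[Path]:
        """JSON report plus one (node, importance, rank) TSV per layer."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = [outdir / "attribution.json"]
        with open(written[0], "wt") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        for layer in LAYERS:
            p = outdir / f"importance_{layer}.tsv"
            with open(p, "wt") as fh:
                fh.write("node_id\timportance\trank\n")
                for rank, (node, score) in enumerate(self.rankings[layer], start=1):
                    fh.write(f"{node}\t{score:.10g}\t{rank}\n")
            written.append(p)
        return written


def attribute(
    params: ModelParams,
    x,
    x0: np.ndarray | None = None,
    target: str = "logit",
    mean_absolute: bool = False,
) -> AttributionReport:
    """Run rescale-rule attribution over a cohort and aggregate per layer."""
    out = deeplift_batch(params, x, x0, target)
    h = params.hierarchy
    names = {"gene": h.genes, "pathway": h.pathways, "compound": h.compounds}
    importance = {
        layer: aggregate_importance(out["contribs"][layer], mean_absolute)
        for layer in LAYERS
    }
    rankings = {
        layer: rank_nodes(importance[layer], names[layer], len(names[layer]))
        for layer in LAYERS
    }
    ref_desc = ("all-zero input across channels" if x0 is None
                else "user-supplied reference input")
    return AttributionReport(
        per_layer_contribs={**{l: out["contribs"][l] for l in LAYERS},
                            "input": out["contribs"]["input"]},
        importance=importance,
        rankings=rankings,
        completeness_residuals=out["residuals"],
        node_names=names,
        reference_description=ref_desc,
        target=target,
        delta_t=out["delta_t"],
    )


def edge_flow_scores(params: ModelParams, importance: dict[str, np.ndarray]) -> dict:
    """Per-edge flow weights for the importance-flow (sankey) visualization.

    Edge score = |effective weight| x source-node importance, normalized to a
    maximum of 1 within each layer pair; only annotated (mask == 1) edges are
    emitted.
    """
    h = params.hierarchy
    out: dict[str, list[dict]] = {}
    specs = [
        ("gene_pathway", params.effective_w_gp(), params.mask_gp,
         h.genes, h.pathways, importance["gene"]),
        ("pathway_compound", params.effective_w_pc(), params.mask_pc,
         h.pathways, h.compounds, importance["pathway"]),
    ]
    for key, w_eff, mask, src_names, dst_names, src_imp in specs:
        scores = np.abs(w_eff) * np.asarray(src_imp, dtype=float)[:, None]
        scores = scores * (mask > 0)
        peak = scores.max()
        if peak > 0:
            scores = scores / peak
        edges = []
        for i, j in zip(*np.nonzero(mask)):
            edges.append({"source": src_names[i], "target": dst_names[j],
                          "score": float(scores[i, j])})
        out[key] = edges
    return out
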