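"""GPC-Net forward model: gene combiner, masked hidden layers, sigmoid heads.

Architecture (five layers): per-gene input features (mutation, amplification,
deletion, methylation) are combined into one gene node each by a grouped
linear map with tanh; the gene layer feeds a pathway layer and the pathway
layer a compound layer, each through a weight matrix Hadamard-masked by the
knowledge hierarchy,

    H_i = tanh(M_i o W_i^T x_i + b_i),

so only annotated gene->pathway and pathway->compound edges carry signal.
A sigmoid predictive head follows every hidden layer; the compound-layer head
is the model's output (the tumour-grade score in [0, 1]), and the training
objective is the alpha-weighted sum of the three heads' binary cross-entropies.

All arithmetic is plain float64 NumPy; gradients live in :mod:`gpcnet.training`.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import HierarchyMap

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "DEFAULT_GRADE_MAP",
    "OmicsTensor",
    "ModelParams",
    "Activations",
    "encode_labels",
    "load_cohort",
    "load_labels",
    "gene_layer_forward",
    "masked_layer_forward",
    "head_forward",
    "forward",
    "bce_loss",
    "total_loss",
    "init_params",
    "make_dense_baseline",
    "save_checkpoint",
    "load_checkpoint",
]

CHANNELS = ("mutation", "amplification", "deletion", "methylation")
N_CHANNELS = 4
BINARY_CHANNELS = (0, 1, 2)
EPS_CLIP = 1e-7

#: tumour differentiation grade -> binary malignancy label
DEFAULT_GRADE_MAP = {
    "well differentiated": 0,
    "well-differentiated": 0,
    "moderately differentiated": 0,
    "moderately-differentiated": 0,
    "poorly differentiated": 1,
    "poorly-differentiated": 1,
    "undifferentiated": 1,
}


# ---------------------------------------------------------------------------
# data containers and loaders
# ---------------------------------------------------------------------------

@dataclass
class OmicsTensor:
    """Samples x genes x 4 channels, gene axis aligned to a HierarchyMap."""

    values: np.ndarray            # N x G x 4, float64, no NaN
    sample_ids: list[str]
    gene_ids: list[str]
    channel_available: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != N_CHANNELS:
            raise ValueError(f"values must be N x G x {N_CHANNELS}")
        if np.isnan(self.values).any():
            raise ValueError("omics tensor contains NaN after loading")
        for j in BINARY_CHANNELS:
            if self.channel_available[j]:
                col = self.values[:, :, j]
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(f"channel '{CHANNELS[j]}' must be binary 0/1")
        if self.channel_available[3]:
            meth = self.values[:, :, 3]
            if meth.min() < 0.0 or meth.max() > 1.0:
                raise ValueError("methylation channel must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: Sequence[int]) -> "OmicsTensor":
        idx = np.asarray(idx, dtype=int)
        return OmicsTensor(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            channel_available=self.channel_available,
        )


def _read_channel(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = [c.strip() for c in df.columns.astype(str)]
    return df


def load_cohort(
    channel_paths: Mapping[str, str | Path],
    gene_ids: Sequence[str] | None = None,
) -> OmicsTensor:
    """Load per-channel samples x genes TSV/CSV files into an OmicsTensor.

    ``channel_paths`` maps channel names (a subset of :data:`CHANNELS`) to
    files; a channel with no file is zero-filled and flagged unavailable,
    which contributes nothing to the gene combiner. Genes are aligned to
    ``gene_ids`` (missing genes zero-filled); samples must agree across files.
    """
    unknown = set(channel_paths) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channel name(s): {sorted(unknown)}")
    if not channel_paths:
        raise ValueError("at least one channel file is required")

    frames = {name: _read_channel(p) for name, p in channel_paths.items()}
    first = next(iter(frames.values()))
    sample_ids = list(first.index)
    for name, df in frames.items():
        if list(df.index) != sample_ids:
            raise ValueError(f"sample IDs in channel '{name}' do not match")
    if gene_ids is None:
        gene_ids = list(first.columns)
    gene_ids = list(gene_ids)

    values = np.zeros((len(sample_ids), len(gene_ids), N_CHANNELS))
    available = [False] * N_CHANNELS
    for name, df in frames.items():
        j = CHANNELS.index(name)
        available[j] = True
        aligned = df.reindex(columns=gene_ids, fill_value=0.0)
        values[:, :, j] = np.nan_to_num(aligned.to_numpy(dtype=np.float64))
    return OmicsTensor(values, sample_ids, gene_ids, tuple(available))


def load_labels(
    path: str | Path,
    sample_ids: Sequence[str],
    grade_map: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Read a (sample ID, grade category) TSV and encode against sample order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} sample(s), e.g. {missing[:3]}")
    categories = df.iloc[:, 0].reindex(list(sample_ids)).astype(str).tolist()
    return encode_labels(categories, grade_map)


def encode_labels(
    grade_text: Sequence[str],
    grade_map: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Map grade categories to {0, 1}: poor/undifferentiated -> 1, else 0.

    Raises on any category absent from the map, listing the offenders.
    """
    mapping = dict(DEFAULT_GRADE_MAP if grade_map is None else grade_map)
    mapping = {k.strip().lower(): int(v) for k, v in mapping.items()}
    out = np.empty(len(grade_text), dtype=np.float64)
    unknown = []
    for i, raw in enumerate(grade_text):
        key = str(raw).strip().lower()
        if key in mapping:
            out[i] = mapping[key]
        else:
            unknown.append(str(raw))
    if unknown:
        raise ValueError(f"unknown grade categor{'y' if len(unknown)==1 else 'ies'}: "
                         f"{sorted(set(unknown))}")
    return out


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """All trainable tensors plus a reference to the masks that gate them.

    The *effective* inter-layer weights are always ``mask * w``; entries at
    mask == 0 are carried but can never influence an output or receive
    gradient. ``activation`` selects tanh (default) or identity hidden units;
    identity exists for the linear-regime attribution checks.
    """

    w_gene: np.ndarray            # G x 4
    b_gene: np.ndarray            # G
    w_gp: np.ndarray              # G x P
    b_p: np.ndarray               # P
    w_pc: np.ndarray              # P x C
    b_c: np.ndarray               # C
    head_gene_w: np.ndarray       # G
    head_gene_b: float
    head_pathway_w: np.ndarray    # P
    head_pathway_b: float
    head_out_w: np.ndarray        # C
    head_out_b: float
    hierarchy: HierarchyMap
    activation: str = "tanh"

    def __post_init__(self) -> None:
        h = self.hierarchy
        expected = {
            "w_gene": (h.n_genes, N_CHANNELS), "b_gene": (h.n_genes,),
            "w_gp": (h.n_genes, h.n_pathways), "b_p": (h.n_pathways,),
            "w_pc": (h.n_pathways, h.n_compounds), "b_c": (h.n_compounds,),
            "head_gene_w": (h.n_genes,), "head_pathway_w": (h.n_pathways,),
            "head_out_w": (h.n_compounds,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if self.activation not in ("tanh", "identity"):
            raise ValueError("activation must be 'tanh' or 'identity'")

    @property
    def mask_gp(self) -> np.ndarray:
        return self.hierarchy.mask_gp

    @property
    def mask_pc(self) -> np.ndarray:
        return self.hierarchy.mask_pc

    def effective_w_gp(self) -> np.ndarray:
        return self.mask_gp * self.w_gp

    def effective_w_pc(self) -> np.ndarray:
        return self.mask_pc * self.w_pc

    def copy(self) -> "ModelParams":
        kwargs = {
            name: np.array(getattr(self, name))
            for name in ("w_gene", "b_gene", "w_gp", "b_p", "w_pc", "b_c",
                         "head_gene_w", "head_pathway_w", "head_out_w")
        }
        return ModelParams(
            hierarchy=self.hierarchy, activation=self.activation,
            head_gene_b=float(self.head_gene_b),
            head_pathway_b=float(self.head_pathway_b),
            head_out_b=float(self.head_out_b),
            **kwargs,
        )


def init_params(
    h: HierarchyMap,
    seed: int | np.random.Generator = 0,
    activation: str = "tanh",
) -> ModelParams:
    """Seeded uniform init in [-1/sqrt(fan_in), +1/sqrt(fan_in)] per layer."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g, p, c = h.n_genes, h.n_pathways, h.n_compounds

    def u(fan_in: int, *shape: int) -> np.ndarray:
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-bound, bound, size=shape)

    return ModelParams(
        w_gene=u(N_CHANNELS, g, N_CHANNELS), b_gene=u(N_CHANNELS, g),
        w_gp=u(g, g, p), b_p=u(g, p),
        w_pc=u(p, p, c), b_c=u(p, c),
        head_gene_w=u(g, g), head_gene_b=float(u(g, 1)[0]),
        head_pathway_w=u(p, p), head_pathway_b=float(u(p, 1)[0]),
        head_out_w=u(c, c), head_out_b=float(u(c, 1)[0]),
        hierarchy=h, activation=activation,
    )


def make_dense_baseline(h: HierarchyMap, seed: int = 0) -> ModelParams:
    """Same architecture with all-ones masks: the fully connected comparator."""
    dense_h = HierarchyMap(
        gene_index=dict(h.gene_index),
        pathway_index=dict(h.pathway_index),
        compound_index=dict(h.compound_index),
        mask_gp=np.ones_like(h.mask_gp),
        mask_pc=np.ones_like(h.mask_pc),
    )
    return init_params(dense_h, seed)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

@dataclass
class Activations:
    h1: np.ndarray    # N x G
    h2: np.ndarray    # N x P
    h3: np.ndarray    # N x C
    p1: np.ndarray    # N
    p2: np.ndarray    # N
    p3: np.ndarray    # N
    # pre-activations, kept for backprop and attribution
    z1: np.ndarray = field(repr=False, default=None)
    z2: np.ndarray = field(repr=False, default=None)
    z3: np.ndarray = field(repr=False, default=None)
    logit1: np.ndarray = field(repr=False, default=None)
    logit2: np.ndarray = field(repr=False, default=None)
    logit3: np.ndarray = field(repr=False, default=None)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else z


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def gene_layer_forward(x: OmicsTensor, params: ModelParams) -> np.ndarray:
    """h1[n,i] = f(sum_j w_gene[i,j] * x[n,i,j] + b_gene[i])."""
    if list(x.gene_ids) != params.hierarchy.genes:
        raise ValueError("omics tensor gene axis is not aligned to the hierarchy")
    z1 = np.einsum("ngj,gj->ng", x.values, params.w_gene) + params.b_gene
    return _act(z1, params.activation)


def masked_layer_forward(
    h_in: np.ndarray, mask: np.ndarray, w: np.ndarray, b: np.ndarray,
    activation: str = "tanh",
) -> np.ndarray:
    """out = f(h_in @ (mask o w) + b); the Hadamard mask enforces sparsity."""
    h_in = np.atleast_2d(np.asarray(h_in, dtype=np.float64))
    if mask.shape != w.shape:
        raise ValueError(f"mask shape {mask.shape} != weight shape {w.shape}")
    if h_in.shape[1] != mask.shape[0] or b.shape[0] != mask.shape[1]:
        raise ValueError("masked layer shape mismatch")
    return _act(h_in @ (mask * w) + b, activation)


def head_forward(h: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Sigmoid predictive head: p = sigma(h @ w + b), elementwise in (0,1)."""
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if h.shape[1] != w.shape[0]:
        raise ValueError("head shape mismatch")
    return _sigmoid(h @ w + b)


def forward(x: OmicsTensor | np.ndarray, params: ModelParams) -> Activations:
    """Full forward pass; the model's prediction is ``p3`` (compound head)."""
    if isinstance(x, OmicsTensor):
        if list(x.gene_ids) != params.hierarchy.genes:
            raise ValueError("omics tensor gene axis is not aligned to the hierarchy")
        values = x.values
    else:
        values = np.asarray(x, dtype=np.float64)
        if values.ndim == 2:
            values = values[None, :, :]
    f = params.activation
    z1 = np.einsum("ngj,gj->ng", values, params.w_gene) + params.b_gene
    h1 = _act(z1, f)
    z2 = h1 @ params.effective_w_gp() + params.b_p
    h2 = _act(z2, f)
    z3 = h2 @ params.effective_w_pc() + params.b_c
    h3 = _act(z3, f)
    logit1 = h1 @ params.head_gene_w + params.head_gene_b
    logit2 = h2 @ params.head_pathway_w + params.head_pathway_b
    logit3 = h3 @ params.head_out_w + params.head_out_b
    return Activations(
        h1=h1, h2=h2, h3=h3,
        p1=_sigmoid(logit1), p2=_sigmoid(logit2), p3=_sigmoid(logit3),
        z1=z1, z2=z2, z3=z3, logit1=logit1, logit2=logit2, logit3=logit3,
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = EPS_CLIP) -> float:
    """Mean binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: predictions {p.shape}, labels {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def total_loss(acts: Activations, y: np.ndarray, alpha: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Weighted multi-head objective: alpha1*H1 + alpha2*H2 + alpha3*H3."""
    a1, a2, a3 = (float(a) for a in alpha)
    if min(a1, a2, a3) < 0 or not np.isfinite([a1, a2, a3]).all():
        raise ValueError("loss weights must be finite and non-negative")
    return (a1 * bce_loss(acts.p1, y)
            + a2 * bce_loss(acts.p2, y)
            + a3 * bce_loss(acts.p3, y))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_PARAM_ARRAYS = ("w_gene", "b_gene", "w_gp", "b_p", "w_pc", "b_c",
                 "head_gene_w", "head_pathway_w", "head_out_w")


def save_checkpoint(params: ModelParams, path: str | Path, config: dict | None = None) -> None:
    """Single-archive checkpoint: arrays + hierarchy (masks, indices) + config."""
    h = params.hierarchy
    meta = {
        "activation": params.activation,
        "head_gene_b": float(params.head_gene_b),
        "head_pathway_b": float(params.head_pathway_b),
        "head_out_b": float(params.head_out_b),
        "genes": h.genes, "pathways": h.pathways, "compounds": h.compounds,
        "hierarchy_hash": h.content_hash(),
        "config": config or {},
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in _PARAM_ARRAYS + ("mask_gp", "mask_pc"):
            arr = getattr(params, name) if name not in ("mask_gp", "mask_pc") else getattr(h, name)
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(name + ".npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for name in _PARAM_ARRAYS + ("mask_gp", "mask_pc"):
            arrays[name] = np.load(io.BytesIO(zf.read(name + ".npy")))
    h = HierarchyMap(
        gene_index={g: i for i, g in enumerate(meta["genes"])},
        pathway_index={p: i for i, p in enumerate(meta["pathways"])},
        compound_index={c: i for i, c in enumerate(meta["compounds"])},
        mask_gp=arrays.pop("mask_gp"), mask_pc=arrays.pop("mask_pc"),
    )
    if h.content_hash() != meta["hierarchy_hash"]:
        raise ValueError("checkpoint hierarchy hash mismatch")
    params = ModelParams(
        hierarchy=h, activation=meta["activation"],
        head_gene_b=meta["head_gene_b"], head_pathway_b=meta["head_pathway_b"],
        head_out_b=meta["head_out_b"], **arrays,
    )
    return params, meta.get("config", {})
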