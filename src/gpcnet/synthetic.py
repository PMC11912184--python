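"""Synthetic hierarchy and multi-omics cohort generator with planted truth.

Emulates the statistical shape of a breast-cancer grading cohort: roughly
balanced binary labels, sparse binary alteration channels (mutation,
amplification, deletion), a continuous methylation channel in [0, 1], and
label signal carried by a small set of driver genes that act through one
planted pathway. Every generated cohort ships with its ground truth, so
driver-recovery and null-calibration experiments are reproducible offline.

The label model: per-sample burden B = sum over driver genes of the three
binary alterations plus a methylation indicator (beta > 0.5); the linear
predictor is eta = beta_effect * B - offset, the offset calibrated so the
Bernoulli(sigmoid(eta)) labels hit the target class balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hierarchy import EdgeList, HierarchyMap, build_hierarchy
from .network import CHANNELS, OmicsTensor

__all__ = ["GeneratorSpec", "GroundTruth", "generate_hierarchy", "generate_cohort",
           "write_cohort"]

GRADE_POS = "poorly differentiated"
GRADE_NEG = "moderately differentiated"


@dataclass
class GeneratorSpec:
    """Study conditions for the simulator (desk-scale mirror of a real cohort)."""

    G: int = 200
    P: int = 20
    C: int = 50
    gp_density: float = 0.05
    pc_density: float = 0.10
    n: int = 2000
    n_drivers: int = 5
    driver_genes: list[str] | None = None     # default: seeded draw of n_drivers
    driver_pathway: str | None = None         # default: first pathway
    effect_size: float = 2.0                  # beta, logit scale per burden unit
    channel_rates: tuple[float, float, float] = (0.10, 0.05, 0.05)
    methylation_params: tuple[float, float] = (2.0, 2.0)
    label_balance: float = 0.5
    balance_tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gp_density <= 1 and 0 < self.pc_density <= 1):
            raise ValueError("edge densities must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_drivers > self.G:
            raise ValueError("more drivers than genes")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.G + 1)]

    def pathway_names(self) -> list[str]:
        return [f"PW{i:02d}" for i in range(1, self.P + 1)]

    def compound_names(self) -> list[str]:
        return [f"CPD{i:03d}" for i in range(1, self.C + 1)]


@dataclass
class GroundTruth:
    driver_genes: list[str]
    driver_pathway: str
    effect_size: float
    offset: float
    linear_predictor: np.ndarray
    label_probs: np.ndarray

    def write(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            json.dump({
                "driver_genes": self.driver_genes,
                "driver_pathway": self.driver_pathway,
                "effect_size": self.effect_size,
                "offset": self.offset,
                "linear_predictor": [float(v) for v in self.linear_predictor],
                "label_probs": [float(v) for v in self.label_probs],
            }, fh, indent=2)


def _resolve_drivers(spec: GeneratorSpec, rng: np.random.Generator) -> tuple[list[str], str]:
    genes = spec.gene_names()
    if spec.driver_genes is not None:
        unknown = set(spec.driver_genes) - set(genes)
        if unknown:
            raise ValueError(f"driver genes not in gene universe: {sorted(unknown)}")
        drivers = list(spec.driver_genes)
    else:
        drivers = sorted(str(g) for g in rng.choice(genes, size=spec.n_drivers, replace=False))
    pathway = spec.driver_pathway or spec.pathway_names()[0]
    if pathway not in spec.pathway_names():
        raise ValueError(f"driver pathway {pathway!r} not in pathway universe")
    return drivers, pathway


def generate_hierarchy(spec: GeneratorSpec, outdir: str | Path | None = None) -> HierarchyMap:
    """Random bipartite masks at the requested densities, with guarantees.

    Every pathway keeps >= 1 member gene and >= 1 downstream compound, and
    every compound >= 1 parent pathway (a pathway with no compound child would
    be disconnected from the output head, so planted signal could never reach
    the prediction). All driver genes are wired into the driver pathway.
    Writes GMT + edge TSV when ``outdir`` is given; byte-stable per seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes, pathways, compounds = spec.gene_names(), spec.pathway_names(), spec.compound_names()
    drivers, driver_pathway = _resolve_drivers(spec, rng)

    mask_gp = rng.random((spec.G, spec.P)) < spec.gp_density
    for j in range(spec.P):          # no empty pathway
        if not mask_gp[:, j].any():
            mask_gp[rng.integers(spec.G), j] = True
    pw_j = pathways.index(driver_pathway)
    for g in drivers:                # drivers act through the planted pathway
        mask_gp[genes.index(g), pw_j] = True

    mask_pc = rng.random((spec.P, spec.C)) < spec.pc_density
    for k in range(spec.C):          # no orphan compound
        if not mask_pc[:, k].any():
            mask_pc[rng.integers(spec.P), k] = True
    for j in range(spec.P):          # no dead-end pathway
        if not mask_pc[j, :].any():
            mask_pc[j, rng.integers(spec.C)] = True

    gp = EdgeList()
    for j, pw in enumerate(pathways):
        gp.groups[pw] = [genes[i] for i in np.flatnonzero(mask_gp[:, j])]
    pc = EdgeList()
    for j, pw in enumerate(pathways):
        pc.groups[pw] = [compounds[k] for k in np.flatnonzero(mask_pc[j, :])]

    h = build_hierarchy(gp, pc, genes)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h.write(outdir / "gene_sets.gmt", outdir / "pathway_compound.tsv")
        h.write_summary(outdir / "hierarchy_summary.json")
    return h


def _burden(values: np.ndarray, driver_cols: np.ndarray) -> np.ndarray:
    """Per-sample driver burden: binary alterations + methylation > 0.5."""
    d = values[:, driver_cols, :]
    return (d[:, :, 0] + d[:, :, 1] + d[:, :, 2] + (d[:, :, 3] > 0.5)).sum(axis=1)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _calibrate_offset(scaled_burden: np.ndarray, balance: float) -> float:
    """Bisection for the offset making mean sigmoid(beta*B - offset) = balance."""
    lo, hi = scaled_burden.min() - 20.0, scaled_burden.max() + 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(scaled_burden - mid).mean() > balance:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    h: HierarchyMap,
    spec: GeneratorSpec,
    outdir: str | Path | None = None,
) -> tuple[OmicsTensor, np.ndarray, GroundTruth]:
    """Draw a cohort with planted driver signal over the given hierarchy."""
    rng = np.random.default_rng(spec.seed)
    drivers, driver_pathway = _resolve_drivers(spec, rng)
    missing = [g for g in drivers if g not in h.gene_index]
    if missing:
        raise ValueError(f"driver genes absent from hierarchy: {missing}")
    genes = h.genes
    n, G = spec.n, len(genes)

    values = np.zeros((n, G, 4))
    for j, rate in enumerate(spec.channel_rates):
        values[:, :, j] = (rng.random((n, G)) < rate).astype(float)
    a, b = spec.methylation_params
    values[:, :, 3] = rng.beta(a, b, size=(n, G))

    driver_cols = np.asarray([h.gene_index[g] for g in drivers], dtype=int)
    eta0 = spec.effect_size * _burden(values, driver_cols)
    offset = _calibrate_offset(eta0, spec.label_balance)
    eta = eta0 - offset
    probs = _sigmoid(eta)

    labels = None
    for attempt in range(50):    # bounded retries to land near the balance target
        draw_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, attempt)))
        candidate = (draw_rng.random(n) < probs).astype(float)
        if abs(candidate.mean() - spec.label_balance) <= spec.balance_tolerance:
            labels = candidate
            break
    if labels is None:
        raise RuntimeError(
            f"could not reach class balance {spec.label_balance} "
            f"+/- {spec.balance_tolerance} in 50 label draws")

    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    x = OmicsTensor(values, sample_ids, list(genes))
    truth = GroundTruth(
        driver_genes=list(drivers), driver_pathway=driver_pathway,
        effect_size=spec.effect_size, offset=float(offset),
        linear_predictor=eta, label_probs=probs,
    )
    if outdir is not None:
        write_cohort(x, labels, truth, outdir)
    return x, labels, truth


def write_cohort(x: OmicsTensor, labels: np.ndarray, truth: GroundTruth,
                 outdir: str | Path) -> dict[str, str]:
    """Write the exact input formats the loaders consume; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for j, name in enumerate(CHANNELS):
        df = pd.DataFrame(x.values[:, :, j], index=x.sample_ids, columns=x.gene_ids)
        path = outdir / f"{name}.tsv"
        if j < 3:
            df.astype(int).to_csv(path, sep="\t", index_label="sample_id")
        else:
            # default float repr is shortest-round-trip: lossless re-parse
            df.to_csv(path, sep="\t", index_label="sample_id")
        manifest[name] = str(path)
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "wt") as fh:
        fh.write("sample_id\tgrade\n")
        for sid, lab in zip(x.sample_ids, labels):
            fh.write(f"{sid}\t{GRADE_POS if lab == 1 else GRADE_NEG}\n")
    manifest["labels"] = str(labels_path)
    truth_path = outdir / "ground_truth.json"
    truth.write(truth_path)
    manifest["ground_truth"] = str(truth_path)
    return manifest
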