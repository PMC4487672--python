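"""Multi-study expression simulator with planted differential structure.

Generates case/control log2 expression matrices for several studies with
three kinds of planted signal, each recorded in a ground-truth object:

* differentially expressed (DE) genes — mean shift of ``de_log2fc`` in cases;
* differentially co-expressed (DC) gene pairs — a pair's two members are
  drawn from a bivariate normal with correlation ``r_case`` in cases and
  ``r_control`` in controls, induced through a shared latent factor
  ``x = sqrt(|r|) z + sqrt(1 - |r|) eps`` (sign applied to one member), which
  hits the target correlation exactly in expectation;
* study batch effects — an additive per-gene offset drawn from
  ``N(0, batch_shift_sd^2)`` in each study.

Planted pairs use disjoint DE genes, so the DC truth is a subset of the DE
truth and no gene sits in two pairs.  All randomness flows from one root
seed; per-study streams are spawned deterministically so the same
configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CASE, CONTROL, ExpressionStudy
from .string_backbone import CHANNELS, combine_scores

BASELINE_MEAN = 8.0  # typical log2 microarray intensity
BASELINE_SD = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults describe the standard planted scenario used throughout the test
    surface: 200 genes, two studies of 30+30 samples (60 per group overall),
    40 DE genes shifted by 4 log2 units against unit noise, and 10 DC pairs
    that are tightly correlated in cases (r=0.9) and independent in controls.
    """

    n_genes: int = 200
    n_studies: int = 2
    samples_per_group_per_study: int = 30
    n_de_genes: int = 40
    de_log2fc: float = 4.0
    n_dc_pairs: int = 10
    r_case: float = 0.9
    r_control: float = 0.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_studies <= 0:
            raise ValueError("n_genes and n_studies must be positive")
        if self.samples_per_group_per_study <= 0:
            raise ValueError("samples_per_group_per_study must be positive")
        if self.n_de_genes < 0 or self.n_dc_pairs < 0:
            raise ValueError("counts must be non-negative")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if 2 * self.n_dc_pairs > self.n_de_genes:
            raise ValueError("planted pairs need 2*n_dc_pairs disjoint DE genes")
        if abs(self.r_case) >= 1 or abs(self.r_control) >= 1:
            raise ValueError("pair correlations must satisfy |r| < 1")
        if self.noise_sd <= 0 or self.batch_shift_sd < 0:
            raise ValueError("noise_sd must be positive, batch_shift_sd >= 0")


@dataclass
class GroundTruth:
    """Planted structure: DE gene ids and DC pairs with their correlations."""

    de_genes: set[str]
    dc_pairs: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for gi, gj in self.dc_pairs:
            if gi == gj:
                raise ValueError("self-pair in ground truth")
            if gi not in self.de_genes or gj not in self.de_genes:
                raise ValueError("DC pair members must be DE genes")

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(p)) for p in self.dc_pairs}


def _correlated_block(rng, r: float, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance series with correlation r via a shared latent factor."""
    z = rng.standard_normal(n_samples)
    e1 = rng.standard_normal(n_samples)
    e2 = rng.standard_normal(n_samples)
    a = np.sqrt(abs(r))
    b = np.sqrt(1.0 - abs(r))
    x = a * z + b * e1
    y = np.sign(r) * a * z + b * e2 if r != 0 else e2
    return x, y


def simulate_studies(config: SimulationConfig) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate the studies and the planted ground truth.

    Returns one ``ExpressionStudy`` per study (cases first, then controls in
    the column order) and a ``GroundTruth`` naming the planted DE genes and
    DC pairs.  Identical configurations produce bit-identical output.
    """
    config.validate()
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    de_genes = genes[: config.n_de_genes]
    pairs = {
        (genes[2 * t], genes[2 * t + 1]): (config.r_case, config.r_control)
        for t in range(config.n_dc_pairs)
    }
    truth = GroundTruth(de_genes=set(de_genes), dc_pairs=pairs)

    root = np.random.SeedSequence(config.seed)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    baseline = BASELINE_MEAN + BASELINE_SD * base_rng.standard_normal(config.n_genes)

    study_seeds = root.spawn(config.n_studies + 1)[1:]
    n = config.samples_per_group_per_study
    de_idx = np.arange(config.n_de_genes)
    studies = []
    for k, seq in enumerate(study_seeds):
        rng = np.random.default_rng(seq)
        batch = rng.standard_normal(config.n_genes) * config.batch_shift_sd
        blocks = {}
        for label, r in ((CASE, config.r_case), (CONTROL, config.r_control)):
            mat = rng.standard_normal((config.n_genes, n))
            for t, (gi, gj) in enumerate(pairs):
                x, y = _correlated_block(rng, r, n)
                mat[2 * t] = x
                mat[2 * t + 1] = y
            mat = mat * config.noise_sd
            mat += (baseline + batch)[:, None]
            if label == CASE:
                mat[de_idx] += config.de_log2fc
            blocks[label] = mat
        sid = f"study{k + 1}"
        cols = [f"{l}_{i + 1:02d}_{sid}" for l in (CASE, CONTROL) for i in range(n)]
        expr = pd.DataFrame(
            np.hstack([blocks[CASE], blocks[CONTROL]]), index=genes, columns=cols
        )
        condition = pd.Series(
            [CASE] * n + [CONTROL] * n, index=cols, name="condition"
        )
        studies.append(ExpressionStudy(study_id=sid, expr=expr, condition=condition))
    return studies, truth


def synthetic_string_links(
    truth: GroundTruth,
    seed: int = 0,
    n_background: int = 30,
    planted_coexpression: tuple[float, float] = (0.6, 0.95),
    background_coexpression: tuple[float, float] = (0.15, 0.5),
) -> pd.DataFrame:
    """Emit a synthetic STRING-style protein-links table (0-1000 dialect).

    Emulates a curated interaction database that covers the true pairs —
    planted DC pairs receive coexpression subscores drawn from
    ``planted_coexpression`` — plus ``n_background`` unrelated edges among
    the DE genes with weaker subscores.  Other channels get small random
    subscores so the combined score differs from the coexpression channel.
    """
    rng = np.random.default_rng(seed)
    de = sorted(truth.de_genes)
    rows = []
    seen = set(truth.pair_set)

    def _row(a: str, b: str, coex: float) -> dict:
        sub = {ch: float(rng.uniform(0.0, 0.2)) for ch in CHANNELS}
        sub["coexpression"] = coex
        rec = {"protein1": a, "protein2": b}
        rec.update({ch: int(round(sub[ch] * 1000)) for ch in CHANNELS})
        rec["combined_score"] = int(round(combine_scores(list(sub.values())) * 1000))
        return rec

    for gi, gj in sorted(truth.pair_set):
        rows.append(_row(gi, gj, float(rng.uniform(*planted_coexpression))))
    target = len(rows) + n_background
    attempts = 0
    while len(rows) < target and attempts < 50 * n_background:
        attempts += 1
        a, b = rng.choice(de, size=2, replace=False)
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        rows.append(_row(key[0], key[1], float(rng.uniform(*background_coexpression))))
    return pd.DataFrame(rows)


def write_study_tsv(study: ExpressionStudy, path) -> None:
    study.expr.to_csv(path, sep="\t", index_label="gene")


def write_labels_tsv(studies: list[ExpressionStudy], path) -> None:
    rows = []
    for s in studies:
        for sample, cond in s.condition.items():
            rows.append({"sample": sample, "condition": cond, "study": s.study_id})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    rows = [
        {"gene_i": gi, "gene_j": gj, "r_case": rc, "r_control": rn}
        for (gi, gj), (rc, rn) in sorted(truth.dc_pairs.items())
    ]
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "r_case", "r_control"]).to_csv(
        path, sep="\t", index=False
    )
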