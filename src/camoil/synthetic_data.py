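"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the study design end to end so every stage can be
tested without any deposited data: three cultivars sampled weekly from the
46th to the 54th week after anthesis with three replicates, ten fatty-acid
species, and a two-cultivar, two-timepoint, two-replicate expression
experiment with homolog structure.

Time-course templates (piecewise linear in weekly knots, % dry mass):

* ``QG-like``  — near-linear oil rise through week 53, then a single-week
  loss of a configurable fraction (default 25%) of the reserve.
* ``M43-like`` — biphasic accumulation peaking at weeks 49 and 52, then a
  default 30% loss by week 54.
* ``HG-like``  — fast early rise, then a plateau with a mild terminal
  increase; after week 50 oleic acid keeps rising at the expense of 16:0
  and 18:2, which makes the FAD2 proxy diverge from KASII/SAD.

Replicate noise is multiplicative lognormal at a configurable CV (default
5%).  Expression counts are negative binomial (dispersion 0.1 by default;
dispersion 0 yields exact noiseless means) around FPKM baselines with
planted group-pattern fold changes for 58 candidate pairs among 400
lipid-pathway homologs, plus off-pathway and non-reciprocal decoys.  Every
generated table carries a truth record sufficient to score the downstream
module that consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deg_screen import LIPID_PATHWAY_KOS, ExpressionTable
from .fame_quant import FATimeCourse, write_timecourse
from .species_registry import DEFAULT_REGISTRY

__all__ = ["ScenarioSpec", "gen_timecourse", "gen_expression", "gen_peak_tables", "write_all"]

WEEKS = tuple(range(46, 55))
SPECIES = DEFAULT_REGISTRY.species_names

# Baseline composition as mass fractions of total oil (oleic-dominant,
# Camellia-like); sums to 1.
BASE_FRACTIONS = {
    "16:0": 0.085,
    "16:1d9": 0.001,
    "16:1d11": 0.006,
    "18:0": 0.020,
    "18:1d9": 0.750,
    "18:1d11": 0.025,
    "18:2": 0.095,
    "18:3": 0.007,
    "20:0": 0.008,
    "20:1d13": 0.003,
}

# Planted expression effect sizes (log2 fold change in HG, in M43) per
# group pattern; counts follow the published candidate-group sizes.
DEFAULT_PLANTED_PLAN: tuple[tuple[str, float, float], ...] = (
    tuple(("I", 2.0, 4.0) for _ in range(6))
    + tuple(("II", -4.0, -2.0) for _ in range(5))
    + tuple(("III", -2.0, 2.0) for _ in range(6))
    + tuple(("IV", -2.5, 0.0) for _ in range(15))
    + tuple(("V", 0.0, 2.5) for _ in range(26))
)

OFFPATH_KOS = ("ko00195", "ko00196", "ko03010", "ko04712")  # photosynthesis etc.


@dataclass(frozen=True)
class ScenarioSpec:
    """All generator knobs, with the study conditions as defaults."""

    seed: int = 0
    cultivars: tuple[str, ...] = ("QG", "HG", "M43")
    noise_cv: float = 0.05
    replicates: int = 3
    loss_qg: float = 0.25
    loss_m43: float = 0.30
    # expression side
    nb_dispersion: float = 0.1
    expr_replicates: int = 2
    n_lipid_pairs: int = 400
    n_offpath_pairs: int = 100
    n_decoys: int = 20
    library_size: float = 2e7
    planted_degs: tuple[tuple[str, float, float], ...] = DEFAULT_PLANTED_PLAN

    def __post_init__(self) -> None:
        if not 0 <= self.loss_qg < 1 or not 0 <= self.loss_m43 < 1:
            raise ValueError("loss fractions must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if len(self.planted_degs) > self.n_lipid_pairs:
            raise ValueError("more planted DEGs than lipid pairs")


# -- fatty-acid time courses -------------------------------------------------


def _qg_template(spec: ScenarioSpec) -> pd.DataFrame:
    totals = np.concatenate([np.linspace(26.0, 44.0, 8), [44.0 * (1 - spec.loss_qg)]])
    return pd.DataFrame(
        {sp: totals * f for sp, f in BASE_FRACTIONS.items()}, index=list(WEEKS)
    )


def _m43_template(spec: ScenarioSpec) -> pd.DataFrame:
    peak = 44.0
    totals = np.array([28.0, 31.0, 34.0, 37.0, 33.5, 37.0, peak, 36.5, peak * (1 - spec.loss_m43)])
    df = pd.DataFrame({sp: totals * f for sp, f in BASE_FRACTIONS.items()}, index=list(WEEKS))
    # 20:1 is decoupled from total oil in this template (a germplasm-specific
    # feature: the paullinic-acid/total-oil correlation holds only in the
    # other two cultivars)
    df["20:1d13"] = [0.10, 0.08, 0.11, 0.09, 0.10, 0.12, 0.09, 0.11, 0.10]
    return df


def _hg_template(spec: ScenarioSpec) -> pd.DataFrame:
    totals = np.array([27.0, 36.0, 38.5, 39.5, 38.8, 39.2, 39.8, 40.3, 41.0])
    df = pd.DataFrame({sp: totals * f for sp, f in BASE_FRACTIONS.items()}, index=list(WEEKS))
    # post-week-50 remodeling: oleic keeps rising at the expense of 16:0 and
    # 18:2 while total oil stays nearly flat -> FAD2 proxy turns discordant
    shift = pd.Series([0.0, 0.0, 0.0, 0.0, 0.0, 0.4, 1.2, 1.5, 2.4], index=list(WEEKS))
    df["18:1d9"] += shift
    df["18:2"] -= 0.6 * shift
    df["16:0"] -= 0.4 * shift
    return df


_TEMPLATES = {"QG": _qg_template, "HG": _hg_template, "M43": _m43_template}


def _noiseless_trajectory(cultivar: str, spec: ScenarioSpec) -> pd.DataFrame:
    try:
        builder = _TEMPLATES[cultivar]
    except KeyError:
        raise ValueError(f"unknown trajectory template {cultivar!r}") from None
    return builder(spec)


def _proxy_sign_pattern(traj: pd.DataFrame) -> dict[str, list[int]]:
    signs = {}
    for enzyme in DEFAULT_REGISTRY.enzymes:
        pool = DEFAULT_REGISTRY.get_pool(enzyme)
        series = traj[[sp for sp in pool]].sum(axis=1).to_numpy()
        signs[enzyme] = [int(np.sign(d)) for d in np.diff(series)]
    return signs


def gen_timecourse(spec: ScenarioSpec) -> tuple[dict[str, FATimeCourse], dict]:
    """Fatty-acid time courses for all cultivars plus the truth record.

    The truth record stores the noiseless trajectories, the per-enzyme
    proxy sign patterns implied by them, and the configured loss fractions.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    courses: dict[str, FATimeCourse] = {}
    truth: dict = {"loss": {"QG": spec.loss_qg, "M43": spec.loss_m43}, "trajectories": {},
                   "proxy_signs": {}}
    for cultivar in spec.cultivars:
        traj = _noiseless_trajectory(cultivar, spec)
        truth["trajectories"][cultivar] = traj.round(12).to_dict()
        truth["proxy_signs"][cultivar] = _proxy_sign_pattern(traj)
        rows = []
        for week in WEEKS:
            for rep in range(1, spec.replicates + 1):
                if spec.noise_cv > 0:
                    factors = rng.lognormal(-(sigma**2) / 2, sigma, size=len(SPECIES))
                else:
                    factors = np.ones(len(SPECIES))
                for sp, f in zip(SPECIES, factors):
                    rows.append(
                        {
                            "week": week,
                            "replicate": rep,
                            "species": sp,
                            "content_pct": traj.loc[week, sp] * f,
                        }
                    )
        courses[cultivar] = FATimeCourse(cultivar, pd.DataFrame(rows))
    return courses, truth


def gen_peak_tables(
    spec: ScenarioSpec,
    courses: dict[str, FATimeCourse] | None = None,
    kernel_mass_mg: float = 10.0,
    is_mass_ug: float = 75.0,
    is_area: float = 1_000_000.0,
) -> pd.DataFrame:
    """Long-format GC-FID peak tables consistent with the time courses.

    Peak areas are back-calculated from the contents so that
    internal-standard quantification recovers the time course exactly
    (unit response factors).
    """
    if courses is None:
        courses, _ = gen_timecourse(spec)
    rows = []
    for cultivar, tc in courses.items():
        for row in tc.data.itertuples(index=False):
            mass_ug = row.content_pct / 100.0 * kernel_mass_mg * 1000.0
            rows.append(
                {
                    "sample_id": f"{cultivar}_w{row.week}_r{row.replicate}",
                    "cultivar": cultivar,
                    "week": row.week,
                    "replicate": row.replicate,
                    "kernel_mass_mg": kernel_mass_mg,
                    "is_mass_ug": is_mass_ug,
                    "is_area": is_area,
                    "species": row.species,
                    "area": mass_ug / is_mass_ug * is_area,
                }
            )
    return pd.DataFrame(rows)


# -- expression experiment ---------------------------------------------------


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + dispersion*mu^2); dispersion 0 is the exact mean."""
    if dispersion == 0:
        return mu.copy()
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p, size=mu.shape).astype(float)


def gen_expression(
    spec: ScenarioSpec,
) -> tuple[ExpressionTable, ExpressionTable, pd.DataFrame, dict[str, set[str]], dict]:
    """Two expression tables, the homolog score matrix, annotation, truth.

    Returns ``(tbl_hg, tbl_m43, scores, annotation, truth)``.  The truth
    record lists every planted candidate pair with its group label and
    log2 fold-change pair, and the decoy genes that must not survive RBH.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_pairs = spec.n_lipid_pairs + spec.n_offpath_pairs
    genes_hg = [f"HG_{i:05d}" for i in range(n_pairs)]
    genes_m43 = [f"M43_{i:05d}" for i in range(n_pairs)]

    # planted effects occupy the first len(planted_degs) lipid pairs
    lfc_hg = np.zeros(n_pairs)
    lfc_m43 = np.zeros(n_pairs)
    groups = ["none"] * n_pairs
    for i, (group, a, b) in enumerate(spec.planted_degs):
        groups[i], lfc_hg[i], lfc_m43[i] = group, a, b
    # some non-candidate lipid pairs move in both cultivars equally
    # (ratio 1), the rest stay flat
    n_planted = len(spec.planted_degs)
    n_coreg = min(40, spec.n_lipid_pairs - n_planted)
    lfc_hg[n_planted : n_planted + n_coreg] = 1.5
    lfc_m43[n_planted : n_planted + n_coreg] = 1.5

    base = 10 ** rng.uniform(0.5, 2.5, size=n_pairs)  # 3-300 FPKM
    lengths_kb = rng.uniform(1.0, 3.0, size=n_pairs)

    def _table(cultivar: str, gene_ids: list[str], lfc: np.ndarray) -> ExpressionTable:
        cols = pd.MultiIndex.from_product(
            [["early", "late"], range(1, spec.expr_replicates + 1)],
            names=["timepoint", "replicate"],
        )
        fpkm = np.empty((n_pairs, 2 * spec.expr_replicates))
        scale = lengths_kb * spec.library_size / 1e6  # FPKM -> expected counts
        for j, tp in enumerate(["early", "late"]):
            mean_fpkm = base * (2.0**lfc if tp == "late" else 1.0)
            mu = mean_fpkm * scale
            for r in range(spec.expr_replicates):
                counts = _nb_counts(rng, mu, spec.nb_dispersion)
                fpkm[:, j * spec.expr_replicates + r] = counts / scale
        return ExpressionTable(cultivar, pd.DataFrame(fpkm, index=gene_ids, columns=cols))

    tbl_hg = _table("HG", genes_hg, lfc_hg)
    tbl_m43 = _table("M43", genes_m43, lfc_m43)

    # similarity scores: strong reciprocal diagonal, weak background, plus
    # non-reciprocal decoy genes on each side
    decoys_hg = [f"HGdecoy_{i:03d}" for i in range(spec.n_decoys)]
    decoys_m43 = [f"M43decoy_{i:03d}" for i in range(spec.n_decoys)]
    idx = genes_hg + decoys_hg
    cols = genes_m43 + decoys_m43
    scores = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(len(idx), len(cols))), index=idx, columns=cols
    )
    diag = 200.0 + rng.uniform(0.0, 100.0, size=n_pairs)
    for i in range(n_pairs):
        scores.iloc[i, i] = diag[i]
    # each decoy's best hit is a paired gene, which prefers its true partner
    for k, d in enumerate(decoys_hg):
        scores.loc[d, genes_m43[k % n_pairs]] = 120.0
    for k, d in enumerate(decoys_m43):
        scores.loc[genes_hg[(k + 7) % n_pairs], d] = 120.0

    annotation: dict[str, set[str]] = {}
    lipid_kos = sorted(LIPID_PATHWAY_KOS)
    for i in range(n_pairs):
        if i < spec.n_lipid_pairs:
            kos = {lipid_kos[int(rng.integers(len(lipid_kos)))]}
        else:
            kos = {OFFPATH_KOS[int(rng.integers(len(OFFPATH_KOS)))]}
        annotation[genes_hg[i]] = set(kos)
        annotation[genes_m43[i]] = set(kos)

    truth = {
        "planted": [
            {
                "gene_hg": genes_hg[i],
                "gene_m43": genes_m43[i],
                "group": groups[i],
                "lfc_hg": float(lfc_hg[i]),
                "lfc_m43": float(lfc_m43[i]),
            }
            for i in range(n_planted)
        ],
        "n_candidates": n_planted,
        "decoys": decoys_hg + decoys_m43,
    }
    return tbl_hg, tbl_m43, scores, annotation, truth


# -- serialization -----------------------------------------------------------


def _expression_to_long(tbl: ExpressionTable) -> pd.DataFrame:
    long = tbl.values.stack(["timepoint", "replicate"], future_stack=True).rename("fpkm").reset_index()
    long.columns = ["gene", "timepoint", "replicate", "fpkm"]
    long.insert(0, "cultivar", tbl.cultivar)
    return long


def write_all(spec: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit every pipeline input (TSV) plus the truth record (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    courses, tc_truth = gen_timecourse(spec)
    tbl_hg, tbl_m43, scores, annotation, expr_truth = gen_expression(spec)

    paths = {
        "peaks": outdir / "peaks.tsv",
        "timecourse": outdir / "timecourse.tsv",
        "expression_hg": outdir / "expression_hg.tsv",
        "expression_m43": outdir / "expression_m43.tsv",
        "scores": outdir / "scores.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    gen_peak_tables(spec, courses).to_csv(
        paths["peaks"], sep="\t", index=False, float_format="%.10g"
    )
    write_timecourse(courses, paths["timecourse"])
    _expression_to_long(tbl_hg).to_csv(
        paths["expression_hg"], sep="\t", index=False, float_format="%.10g"
    )
    _expression_to_long(tbl_m43).to_csv(
        paths["expression_m43"], sep="\t", index=False, float_format="%.10g"
    )
    scores.to_csv(paths["scores"], sep="\t", float_format="%.10g")
    pd.DataFrame(
        [{"gene": g, "ko": "/".join(sorted(kos))} for g, kos in sorted(annotation.items())]
    ).to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({"timecourse": tc_truth, "expression": expr_truth}, fh, indent=1)
    return paths
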