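"""Cross-cultivar differential-expression screen for lipid-pathway genes.

Two cultivars are profiled at an early and a late seed-desiccation
timepoint (two replicates each).  Homologous gene pairs between the two
assemblies are identified by reciprocal best hit (RBH) on a similarity
score matrix.  For each pair the within-cultivar late/early fold change is
computed on FPKM with a pseudo-count, significance is assessed on the log2
scale, and the cross-cultivar *ratio of ratios* — the M43 fold change
divided by the HG fold change — scores how much more a gene is induced in
the oil-losing cultivar.  Pairs with ratio > 2 (or an undefined ratio,
printed as "~", when the denominator cultivar's gene is undetected) that
are annotated to lipid-metabolism KEGG pathways and are not
constant-in-both form the candidate list, partitioned into five expression
patterns:

    I   up in both cultivars          IV  down in HG, constant in M43
    II  down in both                  V   constant in HG, up in M43
    III down in HG, up in M43

"Up" requires fold change > 2 *and* significance; "down" requires fold
change < 0.5 and significance; anything else is "constant" — so a gene
with a 2.4-fold but non-significant change still counts as constant.

Significance: the default is a moderated t-test on log2(FPKM + pseudo)
(per-gene pooled variance shrunk toward the cohort median with a fixed
prior, limma-style), which is what makes a two-replicate design usable;
per-gene Welch's t is available as ``method="welch"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InsufficientDataError

__all__ = [
    "ExpressionTable",
    "HomologPair",
    "DEGRecord",
    "RATIO_UNDEFINED",
    "LIPID_PATHWAY_KOS",
    "GROUPS",
    "rbh_pairs",
    "fold_change",
    "differential_expression",
    "ratio_of_ratios",
    "classify_group",
    "screen",
    "run_screen",
    "ddct_fold",
    "read_expression",
    "load_candidate_table",
]

RATIO_UNDEFINED = "~"  # printed for ratios whose denominator is undetected
GROUPS = ("I", "II", "III", "IV", "V")

# KEGG pathway maps under lipid metabolism (plus the steroid/terpenoid
# branches the screen tracks as TAG-conversion sinks).
LIPID_PATHWAY_KOS = frozenset(
    {
        "ko00061",  # fatty acid biosynthesis
        "ko00062",  # fatty acid elongation
        "ko00071",  # fatty acid degradation
        "ko00072",  # ketone body metabolism
        "ko00073",  # cutin, suberine and wax biosynthesis
        "ko00100",  # steroid biosynthesis
        "ko00120",  # primary bile acid biosynthesis
        "ko00561",  # glycerolipid metabolism
        "ko00564",  # glycerophospholipid metabolism
        "ko00565",  # ether lipid metabolism
        "ko00590",  # arachidonic acid metabolism
        "ko00591",  # linoleic acid metabolism
        "ko00592",  # alpha-linolenic acid metabolism
        "ko00600",  # sphingolipid metabolism
        "ko00909",  # sesquiterpenoid and triterpenoid biosynthesis
        "ko01040",  # biosynthesis of unsaturated fatty acids
    }
)

TIMEPOINTS = ("early", "late")


class ExpressionTable:
    """Gene x sample FPKM matrix for one cultivar at two timepoints.

    Columns are a (timepoint, replicate) MultiIndex with timepoints
    "early" and "late"; at least two replicates per timepoint are required
    and values must be non-negative.
    """

    def __init__(self, cultivar: str, values: pd.DataFrame) -> None:
        if not isinstance(values.columns, pd.MultiIndex):
            raise FormatError("expression values need (timepoint, replicate) columns")
        tps = set(values.columns.get_level_values(0))
        if tps != set(TIMEPOINTS):
            raise FormatError(f"timepoints must be {TIMEPOINTS}, got {sorted(tps)}")
        for tp in TIMEPOINTS:
            if len(values[tp].columns) < 2:
                raise FormatError(f"timepoint {tp!r} needs >= 2 replicates")
        if (values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")
        self.cultivar = cultivar
        self.values = values.sort_index()

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    def gene_values(self, gene: str, timepoint: str) -> np.ndarray:
        if gene not in self.values.index:
            raise LookupError(f"gene {gene!r} not in {self.cultivar} expression table")
        return self.values.loc[gene, timepoint].to_numpy(dtype=float)


def read_expression(path: str | Path, cultivar: str | None = None) -> ExpressionTable:
    """Read a long-format expression TSV (gene, timepoint, replicate, fpkm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "timepoint", "replicate", "fpkm"}
    if not required.issubset(df.columns):
        raise FormatError(f"expression TSV missing columns {required - set(df.columns)}")
    if df.duplicated(["gene", "timepoint", "replicate"]).any():
        raise FormatError("duplicate (gene, timepoint, replicate) keys")
    wide = df.pivot(index="gene", columns=["timepoint", "replicate"], values="fpkm")
    name = cultivar if cultivar is not None else str(df.get("cultivar", pd.Series(["?"])).iloc[0])
    return ExpressionTable(name, wide)


@dataclass(frozen=True)
class HomologPair:
    gene_hg: str
    gene_m43: str
    score: float


@dataclass(frozen=True)
class DEGRecord:
    """One homolog pair with its fold changes, ratio score and group label."""

    pair: HomologPair
    fc_hg: float
    fc_m43: float
    p_hg: float
    p_m43: float
    ratio: float | str
    pathways: frozenset[str]
    group: str = "not_candidate"


# -- RBH pairing -------------------------------------------------------------


def _best_hits(scores: pd.DataFrame) -> dict[str, str]:
    """Best-scoring column per row; ties broken by lexicographically smallest id."""
    best: dict[str, str] = {}
    cols = np.array(scores.columns)
    arr = scores.to_numpy(dtype=float)
    for i, gene in enumerate(scores.index):
        row = arr[i]
        top = row.max(initial=0.0)
        if top <= 0:
            continue
        candidates = cols[row == top]
        best[gene] = sorted(candidates)[0]
    return best


def rbh_pairs(scores: pd.DataFrame) -> list[HomologPair]:
    """Reciprocal-best-hit homolog pairs from a similarity score matrix.

    Rows index one cultivar's genes (HG), columns the other's (M43); higher
    scores mean more similar.  A pair is emitted only when each gene is the
    other's single best hit (after the lexicographic tie-break); each gene
    appears in at most one pair.
    """
    if scores.empty:
        return []
    fwd = _best_hits(scores)
    rev = _best_hits(scores.T)
    pairs = [
        HomologPair(gene_hg=a, gene_m43=b, score=float(scores.loc[a, b]))
        for a, b in fwd.items()
        if rev.get(b) == a
    ]
    return sorted(pairs, key=lambda p: (p.gene_hg, p.gene_m43))


# -- fold changes and significance ------------------------------------------


def fold_change(
    tbl: ExpressionTable, gene: str, pseudo: float = 0.1
) -> tuple[float, float]:
    """Late/early fold change and Welch-t p-value for one gene.

    fc = (mean late FPKM + pseudo) / (mean early FPKM + pseudo); the test is
    Welch's t on log2(FPKM + pseudo).  When both timepoints have zero
    within-group variance the p-value degenerates to 1 (equal means) or 0.
    """
    early = tbl.gene_values(gene, "early")
    late = tbl.gene_values(gene, "late")
    fc = (late.mean() + pseudo) / (early.mean() + pseudo)
    le, ll = np.log2(early + pseudo), np.log2(late + pseudo)
    if le.var(ddof=1) == 0 and ll.var(ddof=1) == 0:
        p = 1.0 if math.isclose(le.mean(), ll.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(ll, le, equal_var=False).pvalue)
    return float(fc), p


def differential_expression(
    tbl: ExpressionTable,
    pseudo: float = 0.1,
    method: str = "moderated",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Fold change and p-value for every gene in the table.

    ``method="moderated"`` (default) shrinks each gene's pooled log2
    variance toward the cohort median with ``prior_df`` prior degrees of
    freedom and tests against a t distribution with (prior + residual) df;
    with two replicates per timepoint this borrows strength across genes
    the way limma does and is far better powered than per-gene Welch.
    ``method="welch"`` applies `fold_change` gene by gene.
    """
    if method == "welch":
        rows = {g: fold_change(tbl, g, pseudo) for g in tbl.genes}
        return pd.DataFrame.from_dict(rows, orient="index", columns=["fc", "p"])
    if method != "moderated":
        raise ValueError(f"unknown method {method!r}")

    early = tbl.values["early"].to_numpy(dtype=float)
    late = tbl.values["late"].to_numpy(dtype=float)
    n1, n2 = early.shape[1], late.shape[1]
    fc = (late.mean(axis=1) + pseudo) / (early.mean(axis=1) + pseudo)
    le, ll = np.log2(early + pseudo), np.log2(late + pseudo)
    diff = ll.mean(axis=1) - le.mean(axis=1)
    resid_df = n1 + n2 - 2
    s2 = (le.var(axis=1, ddof=1) * (n1 - 1) + ll.var(axis=1, ddof=1) * (n2 - 1)) / resid_df
    s2_prior = float(np.median(s2))
    s2_mod = (prior_df * s2_prior + resid_df * s2) / (prior_df + resid_df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    total_df = prior_df + resid_df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    # degenerate zero-variance cohort (noiseless data): exact means decide
    p = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)
    return pd.DataFrame({"fc": fc, "p": p}, index=tbl.values.index)


# -- the cross-cultivar screen ----------------------------------------------


def ratio_of_ratios(fc_hg: float, fc_m43: float) -> float | str:
    """M43 fold change divided by HG fold change; "~" when undefined.

    The sentinel is returned when the HG fold change is (machine) zero or
    either fold change is infinite — i.e. the gene is undetected in one
    condition, as in the "~" entries of the candidate table.
    """
    for fc in (fc_hg, fc_m43):
        if isinstance(fc, str):
            if fc != RATIO_UNDEFINED:
                raise ValueError(f"invalid fold change {fc!r}")
            return RATIO_UNDEFINED
        if fc < 0:
            raise ValueError("fold changes must be non-negative")
    if math.isinf(fc_m43) or math.isinf(fc_hg):
        return RATIO_UNDEFINED
    if fc_hg < 1e-300:
        return RATIO_UNDEFINED
    return fc_m43 / fc_hg


def _status(fc: float | str, p: float, alpha: float) -> str:
    if isinstance(fc, str):  # "~": undetected in the reference condition
        fc = math.inf
    if fc > 2 and p < alpha:
        return "up"
    if fc < 0.5 and p < alpha:
        return "down"
    return "constant"


_GROUP_MAP = {
    ("up", "up"): "I",
    ("down", "down"): "II",
    ("down", "up"): "III",
    ("down", "constant"): "IV",
    ("constant", "up"): "V",
}


def classify_group(
    fc_hg: float | str,
    p_hg: float,
    fc_m43: float | str,
    p_m43: float,
    alpha: float = 0.05,
) -> str:
    """Five-group expression-pattern label from per-cultivar fold changes.

    Per-cultivar status is up (fc > 2, significant), down (fc < 0.5,
    significant) or constant; the (HG, M43) status pair maps to groups
    I..V, any other combination to "other".
    """
    key = (_status(fc_hg, p_hg, alpha), _status(fc_m43, p_m43, alpha))
    return _GROUP_MAP.get(key, "other")


def _ratio_sort_key(ratio: float | str) -> float:
    return math.inf if isinstance(ratio, str) else float(ratio)


def screen(
    records: Iterable[DEGRecord],
    lipid_kos: frozenset[str] | set[str] = LIPID_PATHWAY_KOS,
    cutoff: float = 2.0,
    alpha: float = 0.05,
) -> list[DEGRecord]:
    """Retain lipid-pathway candidates with cross-cultivar ratio > cutoff.

    A record is kept when its ratio exceeds the cutoff (undefined "~"
    ratios are retained — they indicate an extreme imbalance), it is
    annotated to at least one lipid-pathway KEGG map, and it is not
    constant in both cultivars.  Retained records carry their group label
    and are sorted by descending ratio with "~" first.
    """
    if not lipid_kos:
        raise ValueError("lipid_kos must be a non-empty annotation set")
    kept = []
    for rec in records:
        ratio_ok = isinstance(rec.ratio, str) or rec.ratio > cutoff
        if not ratio_ok:
            continue
        if not (rec.pathways & set(lipid_kos)):
            continue
        group = classify_group(rec.fc_hg, rec.p_hg, rec.fc_m43, rec.p_m43, alpha)
        if group == "other" and _status(rec.fc_hg, rec.p_hg, alpha) == "constant" and _status(
            rec.fc_m43, rec.p_m43, alpha
        ) == "constant":
            continue  # constant in both cultivars: not a candidate
        kept.append(replace(rec, group=group))
    return sorted(kept, key=lambda r: -_ratio_sort_key(r.ratio))


def build_records(
    tbl_hg: ExpressionTable,
    tbl_m43: ExpressionTable,
    pairs: Iterable[HomologPair],
    annotation: Mapping[str, set[str]],
    pseudo: float = 0.1,
    method: str = "moderated",
) -> list[DEGRecord]:
    """Per-pair fold changes, p-values, ratios and pathway annotations."""
    de_hg = differential_expression(tbl_hg, pseudo=pseudo, method=method)
    de_m43 = differential_expression(tbl_m43, pseudo=pseudo, method=method)
    records = []
    for pair in pairs:
        if pair.gene_hg not in de_hg.index or pair.gene_m43 not in de_m43.index:
            continue
        fc_hg, p_hg = de_hg.loc[pair.gene_hg]
        fc_m43, p_m43 = de_m43.loc[pair.gene_m43]
        kos = set(annotation.get(pair.gene_hg, set())) | set(
            annotation.get(pair.gene_m43, set())
        )
        records.append(
            DEGRecord(
                pair=pair,
                fc_hg=float(fc_hg),
                fc_m43=float(fc_m43),
                p_hg=float(p_hg),
                p_m43=float(p_m43),
                ratio=ratio_of_ratios(float(fc_hg), float(fc_m43)),
                pathways=frozenset(kos),
            )
        )
    return records


def run_screen(
    tbl_hg: ExpressionTable,
    tbl_m43: ExpressionTable,
    scores: pd.DataFrame,
    annotation: Mapping[str, set[str]],
    lipid_kos: frozenset[str] = LIPID_PATHWAY_KOS,
    cutoff: float = 2.0,
    alpha: float = 0.05,
    pseudo: float = 0.1,
    method: str = "moderated",
) -> list[DEGRecord]:
    """Full pipeline: RBH pairing -> fold changes -> ratio screen."""
    pairs = rbh_pairs(scores)
    records = build_records(tbl_hg, tbl_m43, pairs, annotation, pseudo=pseudo, method=method)
    return screen(records, lipid_kos=lipid_kos, cutoff=cutoff, alpha=alpha)


def records_to_frame(records: Iterable[DEGRecord]) -> pd.DataFrame:
    """Candidate table (ratios rounded to 2 d.p. at output only)."""

    def _fmt(x: float | str) -> str:
        if isinstance(x, str):
            return x
        return f"{x:.2f}" if math.isfinite(x) else RATIO_UNDEFINED

    rows = [
        {
            "gene_hg": r.pair.gene_hg,
            "gene_m43": r.pair.gene_m43,
            "ko": "/".join(sorted(r.pathways)),
            "fc_hg": _fmt(r.fc_hg),
            "fc_m43": _fmt(r.fc_m43),
            "ratio": _fmt(r.ratio),
            "group": r.group,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# -- qPCR arithmetic ---------------------------------------------------------


def ddct_fold(
    ct_target_ref: float,
    ct_housekeeping_ref: float,
    ct_target_test: float,
    ct_housekeeping_test: float,
) -> float:
    """Relative fold difference by the 2^-ddCt method.

    dCt = Ct(target) - Ct(housekeeping) in each sample; the fold difference
    of the test sample relative to the reference is 2^-(dCt_test - dCt_ref).
    """
    ddct = (ct_target_test - ct_housekeeping_test) - (ct_target_ref - ct_housekeeping_ref)
    return 2.0 ** (-ddct)


# -- the transcribed candidate table ----------------------------------------

# Expression-pattern statuses implied by each printed group label; the
# published table prints fold changes and group labels but no p-values, so
# significance flags are reconstructed from the labels (a "constant" label
# on a >2 fold change means the underlying test was not significant).
_GROUP_STATUS = {
    "I": ("up", "up"),
    "II": ("down", "down"),
    "III": ("down", "up"),
    "IV": ("down", "constant"),
    "V": ("constant", "up"),
}


def _parse_fc(text: str) -> float | str:
    text = str(text).strip()
    return RATIO_UNDEFINED if text == RATIO_UNDEFINED else float(text)


def load_candidate_table() -> tuple[list[DEGRecord], pd.DataFrame]:
    """The 58-gene candidate table shipped with the package.

    Returns the rows both as `DEGRecord`s (with significance flags implied
    by the printed group labels: p = 0.01 where the label requires a
    significant change, p = 1.0 where it requires "constant") and as the
    raw DataFrame.  The returned records carry ``group="not_candidate"``;
    running them through `classify_group` / `screen` reproduces the printed
    labels.
    """
    with resources.files("camoil.data").joinpath("candidate_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        fc_hg = _parse_fc(row.fc_hg)
        fc_m43 = _parse_fc(row.fc_m43)
        status_hg, status_m43 = _GROUP_STATUS[row.group]
        p_hg = 1.0 if status_hg == "constant" else 0.01
        p_m43 = 1.0 if status_m43 == "constant" else 0.01
        records.append(
            DEGRecord(
                pair=HomologPair(row.gene_hg, row.gene_m43, score=float("nan")),
                fc_hg=fc_hg,
                fc_m43=fc_m43,
                p_hg=p_hg,
                p_m43=p_m43,
                ratio=ratio_of_ratios(fc_hg, fc_m43),
                pathways=frozenset(str(row.ko).split("/")),
            )
        )
    return records, df
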