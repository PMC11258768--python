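"""Validation statistics for constraint scores against clinical labels.

Given per-variant scores joined to pathogenic/benign labels, this module
reproduces the standard evaluation battery for missense constraint scores:

* enrichment of pathogenic over benign variants in "regions of intolerance"
  (score below a threshold, 0.5 by default), reported as the fold change of
  the two percentages;
* a pooled two-proportion z-test on those proportions;
* Mann-Whitney U comparisons of the score distributions;
* ROC AUC with the orientation that a *low* score predicts pathogenicity;
* stratification by model confidence (pLDDT bands >70 / 50-70 / <50);
* Pearson correlation (e.g. score vs. pLDDT) and per-class empirical CDFs.

Label quality filtering mirrors common ClinVar practice: keep missense
variants with at least two review stars and no conflicting interpretations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PATHOGENIC = "pathogenic"
BENIGN = "benign"


@dataclass(frozen=True)
class LabeledScore:
    """A clinical variant joined to its score — the unit of all statistics."""

    score: float
    label: str
    stars: int = 2
    conflicting: bool = False
    de_novo: bool = False
    plddt: float = 100.0
    consequence: str = "missense"

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if self.label not in (PATHOGENIC, BENIGN):
            raise ValueError(f"label must be pathogenic/benign, got {self.label!r}")
        if self.stars < 0:
            raise ValueError("stars must be >= 0")


def filter_clinical_variants(
    records: Iterable[LabeledScore], min_stars: int = 2
) -> list[LabeledScore]:
    """Keep missense records with enough review stars and no conflicts."""
    return [
        r
        for r in records
        if r.consequence == "missense"
        and r.stars >= min_stars
        and not r.conflicting
    ]


@dataclass
class EnrichmentResult:
    threshold: float
    pathogenic_in: int
    pathogenic_total: int
    benign_in: int
    benign_total: int

    @property
    def pathogenic_pct(self) -> float:
        return 100.0 * self.pathogenic_in / self.pathogenic_total

    @property
    def benign_pct(self) -> float:
        return 100.0 * self.benign_in / self.benign_total

    @property
    def fold_change(self) -> float:
        """pathogenic% / benign%.

        +inf when only the benign intolerant cell is empty; NaN when both
        are (0/0 carries no enrichment information).
        """
        if self.benign_in == 0:
            return math.nan if self.pathogenic_in == 0 else math.inf
        return self.pathogenic_pct / self.benign_pct


def enrichment_from_counts(
    pathogenic_in: int,
    pathogenic_total: int,
    benign_in: int,
    benign_total: int,
    threshold: float = 0.5,
) -> EnrichmentResult:
    """Enrichment directly from a 2x2 contingency of intolerant counts."""
    if pathogenic_total <= 0 or benign_total <= 0:
        raise ValueError("class totals must be positive")
    if not 0 <= pathogenic_in <= pathogenic_total:
        raise ValueError("pathogenic_in outside [0, pathogenic_total]")
    if not 0 <= benign_in <= benign_total:
        raise ValueError("benign_in outside [0, benign_total]")
    return EnrichmentResult(
        threshold=threshold,
        pathogenic_in=pathogenic_in,
        pathogenic_total=pathogenic_total,
        benign_in=benign_in,
        benign_total=benign_total,
    )


def intolerance_enrichment(
    data: Sequence[LabeledScore], threshold: float = 0.5
) -> EnrichmentResult:
    """Fold change of pathogenic% over benign% below the score threshold."""
    path = [r for r in data if r.label == PATHOGENIC]
    ben = [r for r in data if r.label == BENIGN]
    if not path or not ben:
        raise ValueError("both pathogenic and benign records are required")
    return enrichment_from_counts(
        pathogenic_in=sum(r.score < threshold for r in path),
        pathogenic_total=len(path),
        benign_in=sum(r.score < threshold for r in ben),
        benign_total=len(ben),
        threshold=threshold,
    )


def two_proportion_z(in1: int, n1: int, in2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    Returns ``(z, p)``; ``(nan, nan)`` when the pooled proportion is 0 or 1
    (the statistic is undefined there).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 <= in1 <= n1 or not 0 <= in2 <= n2:
        raise ValueError("counts must lie within their sample sizes")
    p1, p2 = in1 / n1, in2 / n2
    pooled = (in1 + in2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return math.nan, math.nan
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def mann_whitney_u(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_a, p)``.

    The exact null distribution is used for small samples without ties;
    otherwise the tie-corrected, continuity-corrected normal approximation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_auc(data: Sequence[LabeledScore]) -> float:
    """AUC for predicting pathogenicity, oriented low score => pathogenic.

    Computed through the rank (Mann-Whitney) identity:
    AUC = P(score_path < score_benign) + 1/2 P(equal).
    """
    path = np.array([r.score for r in data if r.label == PATHOGENIC])
    ben = np.array([r.score for r in data if r.label == BENIGN])
    if path.size == 0 or ben.size == 0:
        raise ValueError("both classes are required to compute an AUC")
    ranks = stats.rankdata(np.concatenate([path, ben]))
    r_path = ranks[: path.size].sum()
    # U counts pathogenic-over-benign wins (+ half-ties); low-score
    # orientation is its complement.
    u_path = r_path - path.size * (path.size + 1) / 2.0
    return float(1.0 - u_path / (path.size * ben.size))


PLDDT_HIGH = 70.0
PLDDT_LOW = 50.0


def plddt_stratify(
    data: Sequence[LabeledScore],
) -> dict[str, list[LabeledScore]]:
    """Partition records by model confidence.

    Bands on the 0-100 pLDDT scale: high (70, 100], medium [50, 70],
    low [0, 50).  Exactly 70 and exactly 50 fall in the medium band.
    """
    out: dict[str, list[LabeledScore]] = {"high": [], "medium": [], "low": []}
    for r in data:
        if not 0.0 <= r.plddt <= 100.0:
            raise ValueError(f"pLDDT {r.plddt} outside [0, 100]")
        if r.plddt > PLDDT_HIGH:
            out["high"].append(r)
        elif r.plddt >= PLDDT_LOW:
            out["medium"].append(r)
        else:
            out["low"].append(r)
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def ecdf_export(data: Sequence[LabeledScore]) -> dict[str, pd.DataFrame]:
    """Per-class empirical CDF tables: (score, cumulative fraction)."""
    if not data:
        raise ValueError("no records")
    out = {}
    for label in (PATHOGENIC, BENIGN):
        scores = np.sort([r.score for r in data if r.label == label])
        if scores.size == 0:
            continue
        uniq, counts = np.unique(scores, return_counts=True)
        frac = np.cumsum(counts) / scores.size
        out[label] = pd.DataFrame({"score": uniq, "cum_fraction": frac})
    return out


# ---------------------------------------------------------------------------
# The full report

@dataclass
class ValidationReport:
    threshold: float
    enrichment: EnrichmentResult
    z: float
    z_p: float
    u: float
    u_p: float
    auc: float
    pearson_r_plddt: float | None
    n_pathogenic: int
    n_benign: int
    mean_pathogenic: float
    mean_benign: float
    de_novo: dict | None
    strata: dict[str, dict]

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and not math.isfinite(v):
                return None if math.isnan(v) else "inf"
            return v

        e = self.enrichment
        return {
            "threshold": self.threshold,
            "n_pathogenic": self.n_pathogenic,
            "n_benign": self.n_benign,
            "pathogenic_intolerant": e.pathogenic_in,
            "pathogenic_total": e.pathogenic_total,
            "pathogenic_pct": round(e.pathogenic_pct, 4),
            "benign_intolerant": e.benign_in,
            "benign_total": e.benign_total,
            "benign_pct": round(e.benign_pct, 4),
            "fold_change": clean(e.fold_change),
            "two_proportion_z": clean(self.z),
            "two_proportion_p": clean(self.z_p),
            "mann_whitney_u": clean(self.u),
            "mann_whitney_p": clean(self.u_p),
            "auc": self.auc,
            "pearson_r_score_plddt": clean(self.pearson_r_plddt)
            if self.pearson_r_plddt is not None
            else None,
            "mean_score_pathogenic": self.mean_pathogenic,
            "mean_score_benign": self.mean_benign,
            "de_novo": self.de_novo,
            "plddt_strata": self.strata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_table_tsv(self, path: str | Path, name: str = "scores") -> None:
        """One-row table in the benign/pathogenic contingency layout."""
        e = self.enrichment
        df = pd.DataFrame(
            [
                {
                    "score": name,
                    "benign_intolerant": e.benign_in,
                    "benign_total": e.benign_total,
                    "benign_pct": round(e.benign_pct, 2),
                    "pathogenic_intolerant": e.pathogenic_in,
                    "pathogenic_total": e.pathogenic_total,
                    "pathogenic_pct": round(e.pathogenic_pct, 2),
                    "fold_change": round(e.fold_change, 2)
                    if math.isfinite(e.fold_change)
                    else ("NA" if math.isnan(e.fold_change) else "inf"),
                    "auc": round(self.auc, 3),
                }
            ]
        )
        df.to_csv(path, sep="\t", index=False)


def build_report(
    data: Sequence[LabeledScore], threshold: float = 0.5
) -> ValidationReport:
    """Run the whole battery on a set of labeled scores.

    ``data`` should already be quality-filtered (see
    :func:`filter_clinical_variants`).  Sub-reports that need both classes
    (per-pLDDT-band tests, de novo comparison) are skipped with ``None``
    entries when a class is missing in the subset.
    """
    path = [r for r in data if r.label == PATHOGENIC]
    ben = [r for r in data if r.label == BENIGN]
    if not path or not ben:
        raise ValueError("both pathogenic and benign records are required")
    enr = intolerance_enrichment(data, threshold)
    z, z_p = two_proportion_z(
        enr.pathogenic_in, enr.pathogenic_total, enr.benign_in, enr.benign_total
    )
    u, u_p = mann_whitney_u([r.score for r in path], [r.score for r in ben])
    auc = roc_auc(data)

    plddts = [r.plddt for r in data]
    scores = [r.score for r in data]
    try:
        r_plddt = pearson_correlation(scores, plddts)
    except ValueError:
        r_plddt = None

    dn = [r for r in path if r.de_novo]
    non_dn = [r for r in path if not r.de_novo]
    de_novo = None
    if dn and non_dn:
        dn_u, dn_p = mann_whitney_u(
            [r.score for r in dn], [r.score for r in non_dn]
        )
        de_novo = {
            "n_de_novo": len(dn),
            "n_other": len(non_dn),
            "mean_de_novo": float(np.mean([r.score for r in dn])),
            "mean_other": float(np.mean([r.score for r in non_dn])),
            "mann_whitney_u": dn_u,
            "mann_whitney_p": dn_p,
        }

    strata = {}
    for band, sub in plddt_stratify(data).items():
        sub_path = [r.score for r in sub if r.label == PATHOGENIC]
        sub_ben = [r.score for r in sub if r.label == BENIGN]
        entry: dict = {"n": len(sub)}
        if sub_path and sub_ben:
            su, sp = mann_whitney_u(sub_path, sub_ben)
            entry.update(mann_whitney_u=su, mann_whitney_p=sp)
        strata[band] = entry

    return ValidationReport(
        threshold=threshold,
        enrichment=enr,
        z=z,
        z_p=z_p,
        u=u,
        u_p=u_p,
        auc=auc,
        pearson_r_plddt=r_plddt,
        n_pathogenic=len(path),
        n_benign=len(ben),
        mean_pathogenic=float(np.mean([r.score for r in path])),
        mean_benign=float(np.mean([r.score for r in ben])),
        de_novo=de_novo,
        strata=strata,
    )


# ---------------------------------------------------------------------------
# Label tables and the score join

LABEL_COLUMNS = [
    "transcript_id", "residue_index", "label", "stars",
    "conflicting", "de_novo", "consequence",
]


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def join_labels_to_scores(
    scores: pd.DataFrame, labels: pd.DataFrame, radius: float
) -> list[LabeledScore]:
    """Join a clinical label table to a score table at one radius.

    Only residues carrying a valid score participate (variants must have a
    score "attached"); labels at unscored or invalid residues are dropped.
    """
    at_r = scores[(scores["radius"] == radius) & scores["valid"]]
    if at_r.empty:
        raise ValueError(f"no valid scores at radius {radius}")
    by_index = at_r.set_index("residue_index")
    out: list[LabeledScore] = []
    for row in labels.itertuples(index=False):
        if row.residue_index not in by_index.index:
            continue
        srow = by_index.loc[row.residue_index]
        out.append(
            LabeledScore(
                score=float(srow["mtr"]),
                label=str(row.label),
                stars=int(row.stars),
                conflicting=bool(row.conflicting),
                de_novo=bool(row.de_novo),
                plddt=float(srow["plddt"]),
                consequence=str(row.consequence),
            )
        )
    return out
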