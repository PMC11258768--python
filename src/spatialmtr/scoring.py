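"""The windowed missense tolerance ratio.

For residue *i* with spherical window *W(i)*, the score is

    MTR_i = [mis_obs / (mis_obs + syn_obs)] / [mis_exp / (mis_exp + syn_exp)]

with all four counts summed over the residues in *W(i)*.  A value of 1
means the window shows exactly the missense fraction expected from its
codons' mutational opportunities; values below 1 indicate missense
depletion (purifying selection), values above 1 missense excess.  Windows
whose combined observed variant total (missense + synonymous) falls below
``min_obs`` carry too little data and are flagged invalid rather than
scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import PerResidueCounts
from .structure import ProteinModel, WindowIndex, build_windows

DEFAULT_RADII = (5.0, 8.0, 11.0, 14.0)
DEFAULT_MIN_OBS = 5


@dataclass
class MtrScore:
    """One residue x one radius scoring result."""

    protein_id: str
    transcript_id: str
    residue_index: int
    aa: str
    radius: float
    value: float  # NaN when invalid
    valid: bool
    w_mis_obs: int
    w_syn_obs: int
    w_mis_exp: int
    w_syn_exp: int
    n_window: int
    plddt: float


@dataclass
class ScoreSet:
    """All scores for one protein/transcript over a set of radii."""

    scores: list[MtrScore]
    radii: tuple[float, ...]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": s.protein_id,
                    "transcript_id": s.transcript_id,
                    "residue_index": s.residue_index,
                    "aa": s.aa,
                    "radius": s.radius,
                    "mtr": s.value,
                    "valid": s.valid,
                    "w_mis_obs": s.w_mis_obs,
                    "w_syn_obs": s.w_syn_obs,
                    "w_mis_exp": s.w_mis_exp,
                    "w_syn_exp": s.w_syn_exp,
                    "n_window": s.n_window,
                    "plddt": s.plddt,
                }
                for s in self.scores
            ]
        )

    def at_radius(self, radius: float) -> list[MtrScore]:
        if radius not in self.radii:
            raise ValueError(f"radius {radius} not in score set {self.radii}")
        return [s for s in self.scores if s.radius == radius]


def window_counts(
    counts: Mapping[int, PerResidueCounts] | Sequence[PerResidueCounts],
    windows: WindowIndex,
    center: int,
) -> tuple[int, int, int, int]:
    """Sum the four count fields over the members of one window.

    Residues lacking counts contribute zero.
    """
    if not isinstance(counts, Mapping):
        counts = {c.residue_index: c for c in counts}
    if center not in windows.members:
        raise KeyError(f"residue {center} not a window center")
    mo = so = me = se = 0
    for j in windows.members[center]:
        c = counts.get(j)
        if c is None:
            continue
        mo += c.mis_obs
        so += c.syn_obs
        me += c.mis_exp
        se += c.syn_exp
    return mo, so, me, se


def compute_mtr(
    w_mis_obs: int,
    w_syn_obs: int,
    w_mis_exp: int,
    w_syn_exp: int,
    min_obs: int = DEFAULT_MIN_OBS,
) -> tuple[float, bool]:
    """Evaluate the ratio for one window; return ``(value, valid)``.

    Invalid (value NaN) when the combined observed total is below
    ``min_obs`` or any denominator — observed total, expected total, or
    expected missense — is zero.  Values above 1 are reported uncapped.
    """
    for name, v in (
        ("w_mis_obs", w_mis_obs), ("w_syn_obs", w_syn_obs),
        ("w_mis_exp", w_mis_exp), ("w_syn_exp", w_syn_exp),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    obs_total = w_mis_obs + w_syn_obs
    exp_total = w_mis_exp + w_syn_exp
    if obs_total < min_obs or obs_total == 0 or exp_total == 0 or w_mis_exp == 0:
        return math.nan, False
    obs_frac = w_mis_obs / obs_total
    exp_frac = w_mis_exp / exp_total
    return obs_frac / exp_frac, True


def score_protein(
    model: ProteinModel,
    counts: Sequence[PerResidueCounts],
    radii: Sequence[float] = DEFAULT_RADII,
    min_obs: int = DEFAULT_MIN_OBS,
    transcript_id: str = "",
    provenance: dict | None = None,
) -> ScoreSet:
    """Score every residue of a model at every radius.

    ``counts`` must already be aligned to the model's residue indices
    (see :func:`spatialmtr.annotation.map_counts_to_model`).
    """
    radii = tuple(float(r) for r in radii)
    if len(radii) != len(set(radii)) or any(r <= 0 for r in radii):
        raise ValueError("radii must be positive and unique")
    by_index = {c.residue_index: c for c in counts}
    scores: list[MtrScore] = []
    for radius in radii:
        windows = build_windows(model, radius)
        for res in model.residues:
            mo, so, me, se = window_counts(by_index, windows, res.index)
            value, valid = compute_mtr(mo, so, me, se, min_obs=min_obs)
            scores.append(
                MtrScore(
                    protein_id=model.protein_id,
                    transcript_id=transcript_id,
                    residue_index=res.index,
                    aa=res.aa,
                    radius=radius,
                    value=value,
                    valid=valid,
                    w_mis_obs=mo,
                    w_syn_obs=so,
                    w_mis_exp=me,
                    w_syn_exp=se,
                    n_window=len(windows.members[res.index]),
                    plddt=res.plddt,
                )
            )
    prov = dict(provenance or {})
    prov.setdefault("min_obs", min_obs)
    prov.setdefault("radii", list(radii))
    return ScoreSet(scores=scores, radii=radii, provenance=prov)


def aggregate_site_scores(
    score_sets: Sequence[ScoreSet], radius: float
) -> dict[int, float]:
    """Per-site mean of valid scores across several score sets.

    Used when multiple models of the same protein each yield a score track;
    residues with no valid score in any set are omitted.
    """
    if not score_sets:
        raise ValueError("no score sets given")
    sums: dict[int, float] = {}
    ns: dict[int, int] = {}
    for ss in score_sets:
        for s in ss.at_radius(radius):
            if not s.valid:
                continue
            sums[s.residue_index] = sums.get(s.residue_index, 0.0) + s.value
            ns[s.residue_index] = ns.get(s.residue_index, 0) + 1
    return {i: sums[i] / ns[i] for i in sorted(sums)}


# ---------------------------------------------------------------------------
# Score tables

SCORE_COLUMNS = [
    "protein_id", "transcript_id", "residue_index", "aa", "radius", "mtr",
    "valid", "w_mis_obs", "w_syn_obs", "w_mis_exp", "w_syn_exp",
    "n_window", "plddt",
]


def write_scores_tsv(score_set: ScoreSet, path: str | Path) -> None:
    """Write a deterministic, byte-stable score table.

    Invalid scores are written as the literal token ``NA`` so that coverage
    accounting (how many residues lacked sufficient data) is reproducible
    from the table alone.
    """
    lines = ["\t".join(SCORE_COLUMNS)]
    for s in sorted(score_set.scores, key=lambda s: (s.radius, s.residue_index)):
        mtr = "NA" if not s.valid else f"{s.value:.6f}"
        lines.append(
            "\t".join(
                [
                    s.protein_id,
                    s.transcript_id,
                    str(s.residue_index),
                    s.aa,
                    f"{s.radius:g}",
                    mtr,
                    "1" if s.valid else "0",
                    str(s.w_mis_obs),
                    str(s.w_syn_obs),
                    str(s.w_mis_exp),
                    str(s.w_syn_exp),
                    str(s.n_window),
                    f"{s.plddt:.2f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Read a score table; the ``mtr`` column is float with NaN for NA."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["valid"] = df["valid"].astype(bool)
    return df
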