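"""Synthetic structures, coding sequences, cohorts and clinical labels.

Everything the scoring and validation pipeline consumes can be generated
here, with controlled geometry and a controlled selection signal:

* an idealized alpha-helical C-alpha trace (consecutive spacing ~3.8 A),
  optionally with a low-confidence extended "disordered tail";
* a random coding sequence with a fixed start codon and no internal stops;
* per-residue observed variants drawn as Poisson counts over each codon's
  possible missense+synonymous changes, with missense observations inside
  a designated intolerant span removed with probability ``suppression``
  (thinning — the simplest model of purifying selection's footprint in
  population data);
* pathogenic/benign labels planted preferentially inside/outside the span,
  with review-star, conflict and de-novo fields populated so the clinical
  quality filters have work to do.

All draws are deterministic functions of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .annotation import (
    NUCLEOTIDES,
    CodingTranscript,
    ObservedVariantRecord,
    SENSE_CODONS,
    SnvConsequence,
    classify_snv,
    write_cds_fasta,
    write_observed_tsv,
)
from .structure import ProteinModel, Residue3D, write_model_pdb

COHORTS = ("cohortA", "cohortB", "cohortC")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the reference planted-signal condition used
    throughout the test suite: a 200-residue protein whose residues 40-60
    form an intolerant span where 90% of missense observations are removed,
    against a cohort depth of 20 expected observations per residue.
    """

    n_residues: int = 200
    seed: int = 42
    helix_radius: float = 2.3  # A
    helix_rise: float = 1.5  # A per residue
    helix_turn_deg: float = 100.0  # degrees per residue
    intolerant_span: tuple[int, int] = (40, 60)  # inclusive, 1-based
    suppression: float = 0.9  # fraction of in-span missense draws removed
    depth: float = 20.0  # expected observed variants per residue
    plddt: float = 90.0  # confidence assigned to helical residues
    disordered_tail: int = 0  # trailing residues re-laid as extended chain
    tail_plddt: float = 30.0
    n_labels: int = 150  # clinical labels to plant
    leakage: float = 0.1  # 0: labels follow the span; 0.5: independent
    star_probs: tuple[float, ...] = (0.05, 0.15, 0.45, 0.20, 0.15)
    conflict_prob: float = 0.10
    de_novo_prob: float = 0.30
    non_missense_frac: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.intolerant_span
        if not (1 <= lo <= hi <= self.n_residues):
            raise ValueError(
                f"intolerant span {self.intolerant_span} outside 1..{self.n_residues}"
            )
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not math.isclose(sum(self.star_probs), 1.0, abs_tol=1e-9):
            raise ValueError("star_probs must sum to 1")

    def in_span(self, residue_index: int) -> bool:
        lo, hi = self.intolerant_span
        return lo <= residue_index <= hi


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent streams so e.g. the CDS does not change when label
    # parameters do
    return np.random.default_rng([config.seed, stream])


def make_cds(n_residues: int, seed: int) -> CodingTranscript:
    """Random CDS: ATG start then ``n-1`` uniform sense codons, no stops."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng([seed, 101])
    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, size=n_residues - 1))
    return CodingTranscript(
        transcript_id=f"SIMTX{n_residues}", cds="".join(codons)
    )


def make_helix_model(
    config: SimulationConfig, sequence: str | None = None
) -> ProteinModel:
    """Idealized helical C-alpha trace matching the configured geometry.

    ``Ca_i = (r cos((i-1)*theta), r sin((i-1)*theta), i*d)``; with the
    default r = 2.3 A, d = 1.5 A, theta = 100 deg the consecutive C-alpha
    spacing is ~3.8 A, as in real protein chains.  The last ``disordered_tail``
    residues instead continue along +z at 3.8 A spacing with low pLDDT,
    mimicking an extended low-confidence terminus.
    """
    n = config.n_residues
    if sequence is None:
        sequence = make_cds(n, config.seed).protein
    if len(sequence) != n:
        raise ValueError("sequence length does not match n_residues")
    theta = math.radians(config.helix_turn_deg)
    r, d = config.helix_radius, config.helix_rise
    n_core = n - config.disordered_tail
    residues = []
    for i in range(1, n + 1):
        if i <= n_core:
            angle = (i - 1) * theta
            coord = (r * math.cos(angle), r * math.sin(angle), i * d)
            plddt = config.plddt
        else:
            coord = (0.0, 0.0, n_core * d + 3.8 * (i - n_core))
            plddt = config.tail_plddt
        residues.append(
            Residue3D(
                index=i, aa=sequence[i - 1],
                ca_coord=np.array(coord), plddt=plddt,
            )
        )
    return ProteinModel(protein_id=f"SIM{n}", residues=residues)


def possible_observed_snvs(
    transcript: CodingTranscript, residue_index: int
) -> list[tuple[int, str, SnvConsequence]]:
    """The missense/synonymous SNVs available at one codon."""
    codon = transcript.codon(residue_index)
    out = []
    for pos in (1, 2, 3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos - 1]:
                continue
            cons = classify_snv(codon, pos, alt)
            if cons in (SnvConsequence.MISSENSE, SnvConsequence.SYNONYMOUS):
                out.append((pos, alt, cons))
    return out


def simulate_observed(
    transcript: CodingTranscript, config: SimulationConfig
) -> list[ObservedVariantRecord]:
    """Draw cohort observations with in-span missense thinning.

    Per residue, Poisson(depth) candidate observations are drawn uniformly
    (with replacement) from the codon's possible missense+synonymous SNVs;
    missense candidates inside the intolerant span survive with probability
    ``1 - suppression``.  Each surviving record is attributed to a random
    cohort, so the distinct/sum counting modes differ on the output.
    """
    rng = _rng(config, 202)
    records: list[ObservedVariantRecord] = []
    for i in range(1, transcript.n_residues + 1):
        options = possible_observed_snvs(transcript, i)
        if not options:
            continue
        k = rng.poisson(config.depth)
        if k == 0:
            continue
        picks = rng.integers(0, len(options), size=k)
        keep_draws = rng.random(size=k)
        codon = transcript.codon(i)
        for pick, u in zip(picks, keep_draws):
            pos, alt, cons = options[pick]
            if (
                cons is SnvConsequence.MISSENSE
                and config.in_span(i)
                and u < config.suppression
            ):
                continue
            records.append(
                ObservedVariantRecord(
                    transcript_id=transcript.transcript_id,
                    residue_index=i,
                    codon_pos=pos,
                    ref_nt=codon[pos - 1],
                    alt_nt=alt,
                    consequence=cons,
                    source=COHORTS[int(rng.integers(0, len(COHORTS)))],
                )
            )
    return records


def make_labeled_variants(
    config: SimulationConfig, transcript_id: str = ""
) -> pd.DataFrame:
    """Plant clinical labels with a configurable link to the span.

    Half the labels are pathogenic, half benign.  A pathogenic label lands
    inside the intolerant span with probability ``1 - leakage`` and a
    benign label outside with the same probability, so ``leakage = 0``
    plants a clean signal and ``leakage = 0.5`` makes positions independent
    of the span (a null).  Review stars follow ``star_probs``; conflicts,
    de-novo status and a small non-missense fraction exercise the quality
    filters downstream.
    """
    rng = _rng(config, 303)
    lo, hi = config.intolerant_span
    span = np.arange(lo, hi + 1)
    outside = np.array(
        [i for i in range(1, config.n_residues + 1) if not config.in_span(i)]
    )
    if outside.size == 0:
        raise ValueError("intolerant span covers the whole protein")
    rows = []
    for j in range(config.n_labels):
        label = "pathogenic" if j % 2 == 0 else "benign"
        favored_in_span = label == "pathogenic"
        follow = rng.random() >= config.leakage
        pick_span = favored_in_span if follow else not favored_in_span
        pool = span if pick_span else outside
        rows.append(
            {
                "transcript_id": transcript_id or f"SIMTX{config.n_residues}",
                "residue_index": int(pool[rng.integers(0, pool.size)]),
                "label": label,
                "stars": int(
                    rng.choice(len(config.star_probs), p=config.star_probs)
                ),
                "conflicting": bool(rng.random() < config.conflict_prob),
                "de_novo": bool(
                    label == "pathogenic" and rng.random() < config.de_novo_prob
                ),
                "consequence": "synonymous"
                if rng.random() < config.non_missense_frac
                else "missense",
            }
        )
    return pd.DataFrame(rows)


def full_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input set (PDB, FASTA, observed TSV, labels TSV).

    The files round-trip losslessly through the package's readers; a copy
    of the configuration is written alongside for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcript = make_cds(config.n_residues, config.seed)
    model = make_helix_model(config, sequence=transcript.protein)
    observed = simulate_observed(transcript, config)
    labels = make_labeled_variants(config, transcript_id=transcript.transcript_id)

    paths = {
        "model": outdir / "model.pdb",
        "cds": outdir / "cds.fasta",
        "observed": outdir / "observed.tsv",
        "labels": outdir / "labels.tsv",
        "config": outdir / "config.yaml",
    }
    write_model_pdb(model, paths["model"])
    write_cds_fasta([transcript], paths["cds"])
    write_observed_tsv(observed, paths["observed"])
    labels.to_csv(paths["labels"], sep="\t", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("intolerant_span", "star_probs"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
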