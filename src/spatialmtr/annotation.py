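"""CDS translation, SNV consequence classification, and variant counts.

The missense tolerance ratio needs, at every residue, four numbers: the
missense and synonymous variants *observed* in population cohorts, and the
missense and synonymous changes *possible* given the codon.  The expected
counts come from exhaustively mutating each codon position to the three
alternative nucleotides (9 single-nucleotide variants per codon) and
classifying each change under the standard genetic code.  This module is a
deliberately small, CDS-level stand-in for a full variant-effect annotator:
no genome coordinates, no splicing, SNVs only.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import IntegrityError, MappingError
from .structure import ProteinModel

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")

# Standard genetic code (NCBI translation table 1), bases in TCAG order.
_TCAG = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(set(CODON_TABLE) - STOP_CODONS))


class SnvConsequence(enum.Enum):
    """Protein-level consequence class of a coding single-nucleotide variant."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOST = "stop_lost"
    OTHER = "other"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class CodingTranscript:
    """A coding sequence and its translation.

    The CDS must be a multiple of 3 with no internal stop codon; a terminal
    stop codon, if present, is excluded from the protein.  A missing ATG
    start only triggers a warning (partial transcripts occur in practice).
    """

    transcript_id: str
    cds: str
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        object.__setattr__(self, "protein", translate_cds(cds))
        if not cds.startswith("ATG"):
            logger.warning(
                "transcript %s does not start with ATG", self.transcript_id
            )

    @property
    def n_residues(self) -> int:
        return len(self.protein)

    def codon(self, residue_index: int) -> str:
        """Codon for a 1-based residue position."""
        if not 1 <= residue_index <= self.n_residues:
            raise IndexError(
                f"residue {residue_index} outside 1..{self.n_residues}"
            )
        start = 3 * (residue_index - 1)
        return self.cds[start : start + 3]


@dataclass
class PerResidueCounts:
    """Observed and expected missense/synonymous counts at one residue."""

    residue_index: int
    mis_obs: int = 0
    syn_obs: int = 0
    mis_exp: int = 0
    syn_exp: int = 0

    def __post_init__(self) -> None:
        for name in ("mis_obs", "syn_obs", "mis_exp", "syn_exp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mis_exp + self.syn_exp > 9:
            raise ValueError("a codon admits at most 9 single-nucleotide variants")


@dataclass(frozen=True)
class ObservedVariantRecord:
    """One distinct coding SNV reported by a cohort."""

    transcript_id: str
    residue_index: int
    codon_pos: int  # 1, 2 or 3 within the codon
    ref_nt: str
    alt_nt: str
    consequence: SnvConsequence
    source: str = ""

    def __post_init__(self) -> None:
        if self.codon_pos not in (1, 2, 3):
            raise ValueError(f"codon_pos must be 1..3, got {self.codon_pos}")
        if self.ref_nt not in NUCLEOTIDES or self.alt_nt not in NUCLEOTIDES:
            raise ValueError("ref/alt must be single nucleotides A/C/G/T")
        if self.ref_nt == self.alt_nt:
            raise ValueError("ref and alt nucleotides are identical")


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    The terminal stop codon (if any) is dropped; an internal stop raises
    :class:`IntegrityError`.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"CDS contains non-ACGT characters: {sorted(bad)}")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for pos, codon in enumerate(codons, 1):
        aa = CODON_TABLE[codon]
        if aa == "*":
            raise IntegrityError(f"internal stop codon {codon} at codon {pos}")
        aas.append(aa)
    return "".join(aas)


def classify_snv(codon: str, codon_pos: int, alt_nt: str) -> SnvConsequence:
    """Consequence of substituting ``alt_nt`` at ``codon_pos`` (1-based)."""
    codon = codon.upper()
    alt_nt = alt_nt.upper()
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon_pos not in (1, 2, 3):
        raise ValueError(f"codon_pos must be 1..3, got {codon_pos}")
    if alt_nt not in NUCLEOTIDES:
        raise ValueError(f"invalid alternative nucleotide {alt_nt!r}")
    if codon[codon_pos - 1] == alt_nt:
        raise ValueError("alternative equals reference nucleotide")
    mutated = codon[: codon_pos - 1] + alt_nt + codon[codon_pos:]
    ref_aa = CODON_TABLE[codon]
    alt_aa = CODON_TABLE[mutated]
    if ref_aa == "*":
        return SnvConsequence.SYNONYMOUS if alt_aa == "*" else SnvConsequence.STOP_LOST
    if alt_aa == "*":
        return SnvConsequence.NONSENSE
    if alt_aa == ref_aa:
        return SnvConsequence.SYNONYMOUS
    return SnvConsequence.MISSENSE


def codon_expected_counts(codon: str) -> tuple[int, int]:
    """(missense, synonymous) counts over all 9 SNVs of one codon.

    Nonsense and stop-lost changes belong to neither class.
    """
    mis = syn = 0
    for pos in (1, 2, 3):
        ref = codon[pos - 1]
        for alt in NUCLEOTIDES:
            if alt == ref:
                continue
            cons = classify_snv(codon, pos, alt)
            if cons is SnvConsequence.MISSENSE:
                mis += 1
            elif cons is SnvConsequence.SYNONYMOUS:
                syn += 1
    return mis, syn


def enumerate_expected(transcript: CodingTranscript) -> list[PerResidueCounts]:
    """Expected counts per residue: every possible SNV of every codon.

    Depends only on the CDS, never on observed data.
    """
    out = []
    for i in range(1, transcript.n_residues + 1):
        mis, syn = codon_expected_counts(transcript.codon(i))
        out.append(PerResidueCounts(residue_index=i, mis_exp=mis, syn_exp=syn))
    return out


def aggregate_observed(
    records: Iterable[ObservedVariantRecord],
    transcript: CodingTranscript,
    mode: str = "distinct",
) -> list[PerResidueCounts]:
    """Observed counts per residue from a cohort variant table.

    mode="distinct" (default) counts each unique (residue, codon position,
    alternative nucleotide) once, however many cohorts report it; mode="sum"
    counts every record.  Records whose consequence is neither missense nor
    synonymous are dropped (with a logged count); a record that contradicts
    the transcript's codon raises :class:`IntegrityError`.
    """
    if mode not in ("distinct", "sum"):
        raise ValueError(f"mode must be 'distinct' or 'sum', got {mode!r}")
    counts: dict[int, PerResidueCounts] = {}
    seen: set[tuple[int, int, str]] = set()
    dropped = 0
    for rec in records:
        if rec.transcript_id != transcript.transcript_id:
            raise IntegrityError(
                f"record for {rec.transcript_id!r} does not match "
                f"transcript {transcript.transcript_id!r}"
            )
        codon = transcript.codon(rec.residue_index)
        if codon[rec.codon_pos - 1] != rec.ref_nt:
            raise IntegrityError(
                f"residue {rec.residue_index}: ref {rec.ref_nt} does not "
                f"match codon {codon} position {rec.codon_pos}"
            )
        true_cons = classify_snv(codon, rec.codon_pos, rec.alt_nt)
        if rec.consequence is not true_cons:
            raise IntegrityError(
                f"residue {rec.residue_index}: recorded consequence "
                f"{rec.consequence} contradicts codon arithmetic ({true_cons})"
            )
        if true_cons not in (SnvConsequence.MISSENSE, SnvConsequence.SYNONYMOUS):
            dropped += 1
            continue
        key = (rec.residue_index, rec.codon_pos, rec.alt_nt)
        if mode == "distinct":
            if key in seen:
                continue
            seen.add(key)
        at = counts.setdefault(
            rec.residue_index, PerResidueCounts(residue_index=rec.residue_index)
        )
        if true_cons is SnvConsequence.MISSENSE:
            at.mis_obs += 1
        else:
            at.syn_obs += 1
    if dropped:
        logger.info("dropped %d records with non-missense/synonymous class", dropped)
    return [counts[i] for i in sorted(counts)]


def merge_counts(
    expected: Sequence[PerResidueCounts], observed: Sequence[PerResidueCounts]
) -> list[PerResidueCounts]:
    """Combine expected-only and observed-only count lists on residue index."""
    obs = {c.residue_index: c for c in observed}
    out = []
    for e in expected:
        o = obs.get(e.residue_index)
        out.append(
            PerResidueCounts(
                residue_index=e.residue_index,
                mis_obs=o.mis_obs if o else 0,
                syn_obs=o.syn_obs if o else 0,
                mis_exp=e.mis_exp,
                syn_exp=e.syn_exp,
            )
        )
    return out


def map_counts_to_model(
    counts: Sequence[PerResidueCounts],
    transcript: CodingTranscript,
    model: ProteinModel,
) -> list[PerResidueCounts]:
    """Align per-residue counts to a structure model by identity.

    The model's residues must match the transcript's protein at every
    modeled position (no alignment heuristics); counts at positions the
    model lacks (e.g. residues without a C-alpha) are dropped.
    """
    n = transcript.n_residues
    for res in model.residues:
        if res.index > n:
            raise MappingError(
                f"model residue {res.index} beyond transcript length {n}"
            )
        expected_aa = transcript.protein[res.index - 1]
        if res.aa != "X" and res.aa != expected_aa:
            raise MappingError(
                f"sequence mismatch at position {res.index}: transcript "
                f"{expected_aa}, model {res.aa}"
            )
    keep = set(model.indices)
    return [c for c in counts if c.residue_index in keep]


# ---------------------------------------------------------------------------
# File formats

def read_cds_fasta(path: str | Path) -> list[CodingTranscript]:
    """Read coding sequences from FASTA (one transcript per record)."""
    transcripts = [
        CodingTranscript(transcript_id=rec.id, cds=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not transcripts:
        raise ValueError(f"{path}: no FASTA records")
    return transcripts


def write_cds_fasta(transcripts: Iterable[CodingTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.cds), 60):
                fh.write(t.cds[i : i + 60] + "\n")


OBSERVED_COLUMNS = [
    "transcript_id", "residue_index", "codon_pos",
    "ref_nt", "alt_nt", "consequence", "source",
]


def read_observed_tsv(path: str | Path) -> list[ObservedVariantRecord]:
    """Read a cohort variant table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(OBSERVED_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ObservedVariantRecord(
                transcript_id=row.transcript_id,
                residue_index=int(row.residue_index),
                codon_pos=int(row.codon_pos),
                ref_nt=row.ref_nt,
                alt_nt=row.alt_nt,
                consequence=SnvConsequence(row.consequence),
                source=getattr(row, "source", "") or "",
            )
        )
    return records


def write_observed_tsv(
    records: Iterable[ObservedVariantRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "residue_index": r.residue_index,
                "codon_pos": r.codon_pos,
                "ref_nt": r.ref_nt,
                "alt_nt": r.alt_nt,
                "consequence": str(r.consequence),
                "source": r.source,
            }
            for r in records
        ],
        columns=OBSERVED_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: Iterable[PerResidueCounts], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "residue_index": c.residue_index,
                "mis_obs": c.mis_obs,
                "syn_obs": c.syn_obs,
                "mis_exp": c.mis_exp,
                "syn_exp": c.syn_exp,
            }
            for c in counts
        ],
        columns=["residue_index", "mis_obs", "syn_obs", "mis_exp", "syn_exp"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[PerResidueCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        PerResidueCounts(
            residue_index=int(r.residue_index),
            mis_obs=int(r.mis_obs),
            syn_obs=int(r.syn_obs),
            mis_exp=int(r.mis_exp),
            syn_exp=int(r.syn_exp),
        )
        for r in df.itertuples(index=False)
    ]
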