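"""FASTA-backed sequence handling for multi-copy 16S rRNA gene families.

Provides degenerate (IUPAC) primer matching against a template, extraction of
the primer-bounded "thermometer" region on which GC content is computed,
GC-content and pairwise-identity calculations, and the default primer set used
throughout the pipeline.

Conventions
-----------
* Coordinates are reported 1-based and inclusive on both ends, matching how
  primer binding positions are conventionally annotated on rRNA genes.
* A primer-bounded region is *inclusive* of both primer binding sites: the
  classic archaeal 109aF (83-99) / 915aR (858-877) pair therefore delimits a
  795 bp region (877 - 83 + 1), and 8aF (3-18) / 1512uR (1424-1442) a 1440 bp
  near-full-length gene.  Although "between the primers" may suggest
  exclusion, the printed amplicon lengths force the inclusive convention.
* Reverse primers are stored 5'->3' as synthesised and are matched against
  the template via their reverse complement.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AmbiguousPrimerSiteError,
    PrimerNotFoundError,
    PrimerOrientationError,
    SequenceError,
    UndefinedValueError,
)

# IUPAC nucleotide ambiguity codes -> sets of unambiguous bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string, IUPAC codes included."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_residues(residues: str, what: str) -> str:
    residues = residues.upper().replace("U", "T")
    if not residues:
        raise SequenceError(f"{what}: empty sequence")
    bad = set(residues) - set(IUPAC_SETS)
    if bad:
        raise SequenceError(f"{what}: illegal characters {sorted(bad)}")
    return residues


@dataclass
class SequenceRecord:
    """One nucleotide sequence (e.g. a 16S rRNA gene paralog such as rrsA).

    Residues are upper-cased and RNA U is normalised to T on ingest; only
    legal IUPAC nucleotide characters are accepted.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = _validate_residues(self.residues, f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3' (possibly degenerate).

    Reverse-orientation primers are stored as synthesised; matching against a
    template uses their reverse complement.
    """

    name: str
    sequence_5to3: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sequence_5to3",
            _validate_residues(self.sequence_5to3, f"primer {self.name!r}"),
        )
        if len(self.sequence_5to3) < 10:
            raise SequenceError(f"primer {self.name!r}: shorter than 10 nt")
        if self.orientation not in ("forward", "reverse"):
            raise SequenceError(
                f"primer {self.name!r}: orientation must be 'forward' or 'reverse'"
            )

    def __len__(self) -> int:
        return len(self.sequence_5to3)

    @property
    def template_query(self) -> str:
        """The strand actually searched for on the template (+ strand)."""
        if self.orientation == "forward":
            return self.sequence_5to3
        return reverse_complement(self.sequence_5to3)


@dataclass(frozen=True)
class PrimerMatch:
    """A primer binding site on a template, 1-based inclusive coordinates."""

    primer_name: str
    start: int
    end: int
    mismatches: int
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class AmpliconRegion:
    """A primer-delimited slice of a parent sequence (1-based inclusive)."""

    parent_id: str
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != self.end - self.start + 1:
            raise SequenceError(
                f"region {self.parent_id}:{self.start}-{self.end}: residue length "
                f"{len(self.residues)} != span {self.end - self.start + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# The primer set used throughout: the archaeal/universal pairs delimiting the
# near-full-length gene (8aF/1512uR) and the thermometer region (109aF/915aR),
# plus the paralog-specific qPCR primers for the H. hispanica rrsA and rrsBC
# 16S genes.
DEFAULT_PRIMERS: dict[str, Primer] = {
    p.name: p
    for p in [
        Primer("8aF", "TCYGGTTGATCCTGCC", "forward"),
        Primer("1512uR", "GGTTACCTTGTTACGACTT", "reverse"),
        Primer("109aF", "AMDGCTCAGTAACACGT", "forward"),
        Primer("915aR", "GTGCTCCCCCGCCAATTCCT", "reverse"),
        Primer("rrsAf", "CGTCCAGCGGAAACTGTCCGG", "forward"),
        Primer("rrsAr", "CCGTCGGGTCCGTCTTCCTGAG", "reverse"),
        Primer("rrsBCf", "GGCGTCCGGTGGAAACTACACAG", "forward"),
        Primer("rrsBCr", "CACTGTCGGGTCCGGTCTCTCAAC", "reverse"),
    ]
}

# Canonical 1-based binding-site starts of the gene-delimiting primers on an
# archaeal 16S rRNA gene, used as simulator defaults.
CANONICAL_PRIMER_STARTS: dict[str, int] = {
    "8aF": 3,
    "109aF": 83,
    "915aR": 858,
    "1512uR": 1424,
}


def _mismatch_count(query: str, window: str) -> int:
    """Positions where the primer-base set and template-base set are disjoint."""
    n = 0
    for q, t in zip(query, window):
        if IUPAC_SETS[q].isdisjoint(IUPAC_SETS[t]):
            n += 1
    return n


def find_primer_site(
    template: SequenceRecord,
    primer: Primer,
    max_mismatch: int = 0,
    strict_unique: bool = False,
) -> PrimerMatch:
    """Locate the best binding site of a (degenerate) primer on a template.

    A position matches when the template base's IUPAC set intersects the
    primer base's set, so degenerate primer codes match any base they denote
    and template ambiguity codes match permissively.  Reverse primers are
    searched as their reverse complement.  The best site has the fewest
    mismatches; ties go to the leftmost site (or raise
    :class:`AmbiguousPrimerSiteError` when ``strict_unique`` is set).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    query = primer.template_query
    tpl = template.residues
    if len(query) > len(tpl):
        raise PrimerNotFoundError(
            f"primer {primer.name!r} longer than template {template.id!r}"
        )
    best = len(query) + 1
    best_positions: list[int] = []
    for i in range(len(tpl) - len(query) + 1):
        mm = _mismatch_count(query, tpl[i : i + len(query)])
        if mm < best:
            best, best_positions = mm, [i]
        elif mm == best:
            best_positions.append(i)
    if best > max_mismatch:
        raise PrimerNotFoundError(
            f"primer {primer.name!r} not found on template {template.id!r} "
            f"(best site has {best} mismatches, allowed {max_mismatch})"
        )
    if strict_unique and len(best_positions) > 1:
        raise AmbiguousPrimerSiteError(
            f"primer {primer.name!r} matches template {template.id!r} at "
            f"{len(best_positions)} equally good sites"
        )
    pos = best_positions[0]
    return PrimerMatch(
        primer_name=primer.name,
        start=pos + 1,
        end=pos + len(query),
        mismatches=best,
        strand="+" if primer.orientation == "forward" else "-",
    )


def extract_thermometer_region(
    template: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 0,
) -> AmpliconRegion:
    """Extract the region delimited by a forward/reverse primer pair.

    The region runs from the first base of the forward site through the last
    base of the reverse site, *inclusive of both primer binding sites* — the
    convention under which 109aF (83-99) / 915aR (858-877) yield the 795 bp
    thermometer region.
    """
    fm = find_primer_site(template, fwd, max_mismatch)
    rm = find_primer_site(template, rev, max_mismatch)
    if fm.start >= rm.start or fm.end >= rm.end:
        raise PrimerOrientationError(
            f"forward primer {fwd.name!r} site ({fm.start}-{fm.end}) is not "
            f"upstream of reverse primer {rev.name!r} site ({rm.start}-{rm.end}) "
            f"on {template.id!r}"
        )
    return AmpliconRegion(
        parent_id=template.id,
        start=fm.start,
        end=rm.end,
        residues=template.residues[fm.start - 1 : rm.end],
    )


def gc_content(seq: Union[AmpliconRegion, SequenceRecord, str]) -> float:
    """GC content (P_GC) as a percentage of counted bases.

    G, C and S (G-or-C) count toward GC; A, T and W (A-or-T) count only in
    the denominator.  All other ambiguity codes straddle the GC/AT split and
    are excluded from numerator and denominator alike, giving an unbiased
    estimate of the underlying GC fraction.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    residues = _validate_residues(residues, "gc_content input")
    gc = sum(residues.count(b) for b in "GCS")
    at = sum(residues.count(b) for b in "ATW")
    if gc + at == 0:
        raise UndefinedValueError("GC content undefined: all bases ambiguous")
    return 100.0 * gc / (gc + at)


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    denominator: str = "alignment",
) -> float:
    """Percent identity from a global end-to-end alignment.

    Identity is the number of identical aligned columns divided by the chosen
    denominator, times 100.  The default denominator is the full alignment
    length (gap columns included); ``"shorter"`` and ``"longer"`` divide by
    the respective sequence length instead.  Scoring parameters default to
    values suited to rRNA-scale similarity and are freely configurable.

    Divergent pairs can have several co-optimal alignments; the argument
    order is canonicalised before aligning so that the reported identity is
    exactly symmetric regardless of which co-optimum the aligner enumerates
    first.
    """
    if denominator not in ("alignment", "shorter", "longer"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if b.residues < a.residues:
        a, b = b, a
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.residues, b.residues)[0]
    identities = aln.counts().identities
    if denominator == "alignment":
        denom = aln.length
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        denom = max(len(a), len(b))
    return 100.0 * identities / denom


def read_fasta(source: Union[str, os.PathLike, io.TextIOBase]) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects."""
    return [
        SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
        for r in SeqIO.parse(source, "fasta")
    ]


def write_fasta(
    records: Iterable[SequenceRecord],
    dest: Union[str, os.PathLike, io.TextIOBase],
) -> None:
    """Write records as unwrapped FASTA (stable byte-for-byte per input)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, dest, "fasta-2line")


def region_table(regions: Sequence[AmpliconRegion]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate regions (id, coordinates, length, GC) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.parent_id for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [len(r) for r in regions],
            "p_gc": [round(gc_content(r), 1) for r in regions],
        }
    )
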