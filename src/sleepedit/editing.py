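"""Prime-editing amplicon quantification.

Reads are globally aligned to the amplicon reference with affine gap costs
and classified into mutually exclusive categories with precedence
``indel > edited > other_sub > unedited``:

* ``indel`` — any insertion or deletion overlapping the quantification
  window;
* ``edited`` — the read carries the *full* programmed substitution set (the
  desired edit plus any silent mutations) and no other difference anywhere
  in the window;
* ``other_sub`` — some other (or partial) substitution pattern in the
  window;
* ``unedited`` — no difference in the window.

Editing rate = edited reads / total aligned reads x100; indel rate = indel
reads / total x100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap global alignment scores.

    A gap of length L costs ``-(gap_open + L * gap_extend)`` (both given as
    positive magnitudes via negative scores below).
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass
class EditSpec:
    """Programmed substitution set and indel-calling window on a reference.

    ``substitutions`` are (0-based position, ref base, alt base); ``window``
    is a half-open [lo, hi) interval on the reference that must contain all
    substitution positions. The default window, when built with
    :meth:`with_default_window`, is the substitution span +-10 nt.
    """

    substitutions: list[tuple[int, str, str]]
    window: tuple[int, int]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise ValueError("edit spec needs at least one substitution")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window must be a non-empty half-open interval")
        for pos, ref, alt in self.substitutions:
            if not (lo <= pos < hi):
                raise ValueError(f"substitution at {pos} outside window "
                                 f"[{lo}, {hi})")
            if ref == alt:
                raise ValueError(f"substitution at {pos} has ref == alt")

    @classmethod
    def with_default_window(cls, substitutions: Sequence[tuple[int, str, str]],
                            reference_length: int, flank: int = 10,
                            name: str = "") -> "EditSpec":
        positions = [p for p, _, _ in substitutions]
        lo = max(0, min(positions) - flank)
        hi = min(reference_length, max(positions) + 1 + flank)
        return cls(substitutions=list(substitutions), window=(lo, hi), name=name)

    def validate_against(self, reference: str) -> None:
        ref = reference.upper()
        if self.window[1] > len(ref):
            raise ValueError("window extends past the reference")
        for pos, r, _ in self.substitutions:
            if ref[pos] != r.upper():
                raise ValueError(
                    f"reference base at {pos} is {ref[pos]}, spec says {r}")

    def apply_to(self, reference: str) -> str:
        """Reference sequence with the full programmed edit installed."""
        self.validate_against(reference)
        seq = list(reference.upper())
        for pos, _, alt in self.substitutions:
            seq[pos] = alt.upper()
        return "".join(seq)

    @property
    def substitution_set(self) -> frozenset[tuple[int, str]]:
        return frozenset((p, a.upper()) for p, _, a in self.substitutions)

    @classmethod
    def parse(cls, text: str, window: tuple[int, int] | None = None,
              reference_length: int | None = None, name: str = "") -> "EditSpec":
        """Parse ``"pos:ref>alt[,pos:ref>alt...]"`` (0-based positions)."""
        subs = []
        for part in text.split(","):
            pos_s, change = part.strip().split(":")
            ref, alt = change.split(">")
            subs.append((int(pos_s), ref.upper(), alt.upper()))
        if window is None:
            if reference_length is None:
                raise ValueError("need window or reference_length")
            return cls.with_default_window(subs, reference_length, name=name)
        return cls(substitutions=subs, window=window, name=name)


@dataclass
class Alignment:
    """Pairwise global alignment as gapped reference/read strings."""

    ref_gapped: str
    read_gapped: str
    score: float


@dataclass
class ReadClass:
    """Per-read category with its supporting alignment."""

    category: str
    aligned: Alignment | None = None


@dataclass
class EditingResult:
    """Read-category counts and rates on the printed percent scale."""

    n_total: int
    n_edited: int
    n_indel: int
    n_unedited: int
    n_other: int
    name: str = ""

    def __post_init__(self) -> None:
        parts = self.n_edited + self.n_indel + self.n_unedited + self.n_other
        if parts != self.n_total:
            raise ValueError("category counts must sum to n_total")

    @property
    def editing_pct(self) -> float:
        return 100.0 * self.n_edited / self.n_total

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.n_indel / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample": self.name, "n_total": self.n_total,
            "n_edited": self.n_edited, "n_indel": self.n_indel,
            "n_unedited": self.n_unedited, "n_other": self.n_other,
            "editing_pct": self.editing_pct, "indel_pct": self.indel_pct,
        }])


def _check_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters: {sorted(bad)}")
    return seq


def _make_aligner(scoring: AlignScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # biopython charges open_gap_score for the first gap base and
    # extend_gap_score for each further one; our convention charges
    # open + extend for the first base
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_read(read: str, reference: str,
               scoring: AlignScoring | None = None) -> Alignment:
    """Optimal global alignment of a read to the reference (affine gaps).

    Ties are broken deterministically by taking the aligner's first
    reported optimum.
    """
    scoring = scoring or AlignScoring()
    read = _check_sequence(read, "read")
    reference = _check_sequence(reference, "reference")
    aligner = _make_aligner(scoring)
    aln = aligner.align(reference, read)[0]
    return Alignment(ref_gapped=str(aln[0]), read_gapped=str(aln[1]),
                     score=float(aln.score))


def classify(alignment: Alignment, spec: EditSpec) -> ReadClass:
    """Classify one aligned read (precedence indel > edited > other_sub >
    unedited).

    Deletions of reference positions inside [lo, hi) and insertions at
    interior boundary points (strictly between lo and hi) count as indels.
    """
    lo, hi = spec.window
    ref_g, read_g = alignment.ref_gapped, alignment.read_gapped
    ref_len = sum(1 for ch in ref_g if ch != "-")
    if hi > ref_len:
        raise ValueError("window extends past the aligned reference")

    subs_in_window: set[tuple[int, str]] = set()
    indel = False
    rpos = 0  # next reference position
    for rc, qc in zip(ref_g, read_g):
        if rc == "-":  # insertion before reference position rpos
            if lo < rpos < hi:
                indel = True
        elif qc == "-":  # deletion of reference position rpos
            if lo <= rpos < hi:
                indel = True
            rpos += 1
        else:
            if rc != qc and lo <= rpos < hi:
                subs_in_window.add((rpos, qc))
            rpos += 1

    if indel:
        cat = "indel"
    elif subs_in_window == spec.substitution_set:
        cat = "edited"
    elif subs_in_window:
        cat = "other_sub"
    else:
        cat = "unedited"
    return ReadClass(category=cat, aligned=alignment)


def quantify(reads: Iterable[str], reference: str, spec: EditSpec,
             scoring: AlignScoring | None = None, name: str = "",
             return_classes: bool = False
             ) -> EditingResult | tuple[EditingResult, list[str]]:
    """Classify a read set and compute editing/indel rates.

    Reads that equal the reference or the fully edited reference byte-for-
    byte skip the aligner (their optimal alignment is gap-free and their
    category follows directly); everything else is aligned and classified.
    """
    reference = _check_sequence(reference, "reference")
    spec.validate_against(reference)
    edited_ref = spec.apply_to(reference)
    counts = {"edited": 0, "indel": 0, "unedited": 0, "other_sub": 0}
    categories: list[str] = []
    n = 0
    for read in reads:
        n += 1
        read = read.upper()
        if read == reference:
            cat = "unedited"
        elif read == edited_ref:
            cat = "edited"
        else:
            cat = classify(align_read(read, reference, scoring), spec).category
        counts[cat] += 1
        if return_classes:
            categories.append(cat)
    if n == 0:
        raise ValueError("empty read set")
    result = EditingResult(n_total=n, n_edited=counts["edited"],
                           n_indel=counts["indel"],
                           n_unedited=counts["unedited"],
                           n_other=counts["other_sub"], name=name)
    return (result, categories) if return_classes else result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> str:
    """First record of a FASTA file as the amplicon reference."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTQ or FASTA (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(r.seq).upper() for r in SeqIO.parse(str(path), fmt)]
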