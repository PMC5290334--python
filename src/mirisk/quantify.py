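"""Exact-substring quantification of mature miRNAs within reads.

Mature miRNA sequences (miRBase mature dialect) are sought as exact,
contiguous substrings of each read; a read containing a given miRNA
sequence increments that miRNA's count once, regardless of how many times
the sequence occurs in the read, and a read containing several distinct
miRNA sequences increments each of them.  No mismatches, no
reverse-complement search (small-RNA libraries are strand-resolved).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

_RNA_ALPHABET = frozenset("ACGU")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class MatureMirna(NamedTuple):
    """A named mature miRNA sequence over the RNA alphabet {A,C,G,U}."""

    id: str
    sequence: str


def canonicalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert T->U, strip non-letter noise, validate alphabet.

    Punctuation and whitespace occasionally contaminate published
    sequences (e.g. stray underscores); they are removed.  Letters other
    than A/C/G/U/T are rejected.
    """
    cleaned = "".join(c for c in seq.upper() if c.isalpha()).replace("T", "U")
    bad = set(cleaned) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)}")
    return cleaned


def load_mature_fasta(path) -> list[MatureMirna]:
    """Read mature miRNAs from FASTA; ids are the first header token.

    DNA-alphabet records are converted to RNA (T->U); duplicate ids are
    rejected.  An empty file yields an empty list.
    """
    _validate_fasta_shape(path)
    mirnas: list[MatureMirna] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        mid = record.id
        if mid in seen:
            raise ValueError(f"duplicate miRNA id in FASTA: {mid!r}")
        seen.add(mid)
        seq = canonicalize_rna(str(record.seq), context=mid)
        if not seq:
            raise ValueError(f"empty sequence for miRNA {mid!r}")
        mirnas.append(MatureMirna(mid, seq))
    return mirnas


def _validate_fasta_shape(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>'"
                    )
                return


def _read_sequences(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        s = str(r.seq) if hasattr(r, "seq") else str(r)
        out.append(canonicalize_rna(s, context="read"))
    return out


def count_exact_matches(reads: Iterable, mirnas: Sequence[MatureMirna]) -> pd.Series:
    """Per-miRNA count of reads containing its sequence as a substring.

    ``reads`` may be strings or Biopython ``SeqRecord`` objects.  Returns
    an integer Series indexed by miRNA id, in panel order.
    """
    seqs = _read_sequences(reads)
    counts = pd.Series(0, index=[m.id for m in mirnas], dtype=int)
    for read in seqs:
        for m in mirnas:
            if m.sequence in read:
                counts[m.id] += 1
    return counts


def trim_mirnas(
    mirnas: Sequence[MatureMirna], five_prime: int = 2, three_prime: int = 4
) -> list[MatureMirna]:
    """Trim bases off both ends of each canonical sequence.

    The defaults (2 nt at 5', 4 nt at 3') produce the trimmed-isoform
    proxy used to probe isomiR diversity: shorter probes can only gain
    substring matches, never lose them.
    """
    if five_prime < 0 or three_prime < 0:
        raise ValueError("trim lengths must be nonnegative")
    cut = five_prime + three_prime
    out = []
    for m in mirnas:
        if len(m.sequence) <= cut:
            raise ValueError(
                f"miRNA {m.id!r} is too short ({len(m.sequence)} nt) to trim {cut} bases"
            )
        end = len(m.sequence) - three_prime
        out.append(MatureMirna(m.id, m.sequence[five_prime:end]))
    return out


def exclude_low_abundance_samples(
    counts: pd.DataFrame, min_total_reads: int
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose total read count falls below a threshold.

    Column order of the kept samples is preserved.  Raises if every
    sample would be excluded, since the downstream analysis is then
    undefined.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    totals = counts.sum(axis=0)
    keep = totals >= min_total_reads
    excluded = [s for s in counts.columns if not keep[s]]
    if not keep.any():
        raise ValueError("all samples fall below the abundance threshold")
    return counts.loc[:, keep], excluded


def write_fastq(records, path) -> None:
    """Serialize reads as FASTQ (constant quality already attached)."""
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    """Load reads from FASTQ as SeqRecords."""
    return list(SeqIO.parse(str(path), "fastq"))
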