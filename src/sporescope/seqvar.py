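"""Variability summaries and SNP calls for DNA multiple alignments.

Works on small Sanger-style multilocus alignments (a few dozen sequences)
where polymorphic positions are screened with a minimum variant-frequency
threshold rather than a probabilistic caller.  Gaps and IUPAC ambiguity
codes are excluded from frequency denominators by default, so a column
whose only variation is gap-vs-base is never reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

from .errors import InputFormatError, ValidationError

UNAMBIGUOUS = frozenset("ACGT")
GAPS = frozenset("-.")


@dataclass
class MultipleAlignment:
    """Equal-length DNA sequence records with unique ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and sequences differ in number")
        if len(self.seqs) < 2:
            raise ValidationError("alignment needs at least two sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            ragged = [i for i, s in zip(self.ids, self.seqs)
                      if len(s) != len(self.seqs[0])]
            raise ValidationError(
                f"sequences are not equal length (offending ids: {ragged})"
            )
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    def column(self, i: int) -> str:
        """0-based column as a string of residues."""
        return "".join(s[i] for s in self.seqs)


@dataclass(frozen=True)
class SiteSummary:
    n_sites: int
    n_variable: int
    n_parsimony_informative: int

    @property
    def percent_variable(self) -> float:
        return round(100.0 * self.n_variable / self.n_sites, 1)


@dataclass(frozen=True)
class SnpCall:
    """A polymorphic alignment column (1-based position)."""

    position: int
    ref: str                       # majority base
    variants: dict[str, float] = field(default_factory=dict)  # base -> freq


def read_fasta_alignment(path: str | Path) -> MultipleAlignment:
    """Read and validate a FASTA multiple alignment (case-normalized)."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"alignment file not found: {path}")
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        # AlignIO rejects ragged records; re-read loosely for a better message
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) >= 2:
            lengths = {len(r.seq) for r in records}
            if len(lengths) > 1:
                ref_len = len(records[0].seq)
                ragged = [r.id for r in records if len(r.seq) != ref_len]
                raise ValidationError(
                    f"unequal sequence lengths in {path} (offending ids: {ragged})"
                ) from exc
        raise InputFormatError(f"could not read alignment {path}: {exc}") from exc
    return MultipleAlignment(
        ids=[rec.id for rec in aln], seqs=[str(rec.seq) for rec in aln]
    )


def _retained(column: Iterable[str], gap_policy: str) -> list[str]:
    if gap_policy == "ignore":
        return [b for b in column if b in UNAMBIGUOUS]
    if gap_policy == "strict":
        # drop the whole column if any residue is a gap or ambiguity code
        col = list(column)
        if any(b not in UNAMBIGUOUS for b in col):
            return []
        return col
    raise ValidationError(f"unknown gap_policy {gap_policy!r}")


def count_variable_sites(
    aln: MultipleAlignment, gap_policy: str = "ignore"
) -> SiteSummary:
    """Count variable and parsimony-informative columns.

    A column is variable when at least two distinct unambiguous bases occur
    among the retained residues, and parsimony-informative when at least
    two bases each occur in at least two sequences.
    """
    n_var = n_pi = n_retained = 0
    for i in range(aln.length):
        col = _retained(aln.column(i), gap_policy)
        if not col:
            continue
        n_retained += 1
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pi += 1
    if n_retained == 0:
        raise ValidationError("no columns retained under the gap policy")
    return SiteSummary(
        n_sites=aln.length, n_variable=n_var, n_parsimony_informative=n_pi
    )


def call_snps(
    aln: MultipleAlignment,
    min_variant_freq: float = 0.25,
    gap_policy: str = "ignore",
) -> list[SnpCall]:
    """Report columns whose top non-majority base reaches the frequency cut.

    Frequencies are computed over retained residues only.  The threshold
    boundary is inclusive (>=), so with four sequences a singleton variant
    at exactly 25% is called at the default cut.
    """
    if not 0 < min_variant_freq <= 1:
        raise ValidationError("min_variant_freq must be in (0, 1]")
    calls: list[SnpCall] = []
    for i in range(aln.length):
        col = _retained(aln.column(i), gap_policy)
        if len(col) < 2:
            continue
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        if len(counts) < 2:
            continue
        total = len(col)
        # majority base; ties broken alphabetically for determinism
        ref = max(sorted(counts), key=lambda b: counts[b])
        variants = {
            b: counts[b] / total for b in sorted(counts)
            if b != ref and counts[b] / total >= min_variant_freq
        }
        if variants:
            calls.append(SnpCall(position=i + 1, ref=ref, variants=variants))
    return calls


def snp_table_rows(calls: list[SnpCall]) -> list[dict]:
    """Flatten SNP calls for TSV export (position, ref, alt, alt_freq)."""
    rows = []
    for call in calls:
        for alt, freq in call.variants.items():
            rows.append({"position": call.position, "ref": call.ref,
                         "alt": alt, "alt_freq": freq})
    return rows
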