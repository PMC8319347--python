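"""Multi-caller variant consensus filtering and mutation impact classes.

Variant call sets produced independently by several callers (e.g. GATK,
Varscan, bcftools) are merged into a consensus set: a variant is retained
when at least ``min_callers`` callers report it and its consensus
frequency (median across the reporting callers) is at least
``min_frequency``.  Impact classification maps controlled annotation terms
onto HIGH / MODERATE / LOW classes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MutationCall",
    "IMPACT_CLASSES",
    "consensus_calls",
    "classify_impact",
    "read_caller_vcf",
    "write_consensus_tsv",
    "read_consensus_tsv",
]


@dataclass(frozen=True)
class MutationCall:
    """A single variant call.

    ``locus`` is a gene id or an intergenic id (e.g. ``IG_184033``);
    identity for consensus matching is ``(chrom, position, alt)``.
    """

    locus: str
    position: int
    ref: str
    alt: str
    frequency: float
    callers: frozenset[str]
    annotation: str = "nonsynonymous_coding"
    line: str = ""
    generation: int = 0
    chrom: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.position < 1:
            raise ValueError(f"position {self.position} < 1")
        if not self.callers:
            raise ValueError("callers must be nonempty")
        object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity key used for cross-caller matching."""
        return (self.chrom, self.line, self.position, self.alt)


#: Annotation term -> impact class (total mapping; unknown terms are an error).
IMPACT_CLASSES: dict[str, str] = {
    "frameshift": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_gained": "HIGH",
    "start_lost": "HIGH",
    "codon_deletion": "MODERATE",
    "codon_insertion_or_change": "MODERATE",
    "nonsynonymous_coding": "MODERATE",
    "synonymous_coding": "LOW",
    "nonsynonymous_start": "LOW",
}


def classify_impact(annotation: str) -> str:
    """Map a controlled annotation term to HIGH / MODERATE / LOW.

    Gain or loss of start/stop codons and frameshifts are HIGH impact;
    codon-level indels/changes and nonsynonymous coding changes are
    MODERATE; synonymous and nonsynonymous-start changes are LOW.
    Unknown terms raise ``ValueError`` rather than defaulting silently.
    """
    try:
        return IMPACT_CLASSES[annotation]
    except KeyError:
        raise ValueError(
            f"unknown annotation term {annotation!r}; "
            f"supported: {sorted(IMPACT_CLASSES)}"
        ) from None


def consensus_calls(
    per_caller_sets: Sequence[Iterable[MutationCall]],
    min_callers: int = 2,
    min_frequency: float = 0.20,
) -> list[MutationCall]:
    """Merge per-caller call sets into a consensus set.

    A variant (identified by chrom/line, position and alt allele) is kept
    when reported by >= ``min_callers`` callers and its median frequency
    across the reporting callers is >= ``min_frequency``.  The frequency
    filter is applied to the consensus (median) frequency; the union of
    reporting callers is recorded on the returned call.

    The result is independent of the ordering of ``per_caller_sets`` and
    idempotent: feeding the output back through with the same thresholds
    returns it unchanged.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    sets = [list(s) for s in per_caller_sets]
    if not sets:
        raise ValueError("no caller sets provided")

    grouped: dict[tuple, list[MutationCall]] = {}
    for calls in sets:
        for call in calls:
            grouped.setdefault(call.key, []).append(call)

    out: list[MutationCall] = []
    for key in sorted(grouped):
        calls = grouped[key]
        callers = frozenset().union(*(c.callers for c in calls))
        if len(callers) < min_callers:
            continue
        freq = float(statistics.median(c.frequency for c in calls))
        if freq < min_frequency:
            continue
        rep = min(calls, key=lambda c: sorted(c.callers))
        out.append(replace(rep, frequency=freq, callers=callers))
    return out


# ---------------------------------------------------------------------------
# I/O: per-caller VCF subset and consensus TSV


def read_caller_vcf(path: str | Path, caller: str | None = None) -> list[MutationCall]:
    """Read a per-caller VCF subset (CHROM, POS, REF, ALT, INFO AF/GENE/ANN).

    ``caller`` defaults to the file stem.  Multiallelic records are split
    into one :class:`MutationCall` per alt allele.
    """
    import pysam

    path = Path(path)
    name = caller or path.stem
    calls: list[MutationCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            afs = rec.info.get("AF", (0.0,))
            if not isinstance(afs, tuple):
                afs = (afs,)
            gene = rec.info.get("GENE", rec.chrom)
            ann = rec.info.get("ANN", "nonsynonymous_coding")
            line = rec.info.get("LINE", "")
            gen = int(rec.info.get("GEN", 0))
            for alt, af in zip(rec.alts or (), afs):
                calls.append(
                    MutationCall(
                        locus=str(gene),
                        position=rec.pos,
                        ref=rec.ref or "N",
                        alt=str(alt),
                        frequency=float(af),
                        callers=frozenset({name}),
                        annotation=str(ann),
                        line=str(line),
                        generation=gen,
                        chrom=rec.chrom,
                    )
                )
    return calls


_TSV_COLUMNS = [
    "chrom", "position", "ref", "alt", "locus", "frequency",
    "callers", "annotation", "line", "generation",
]


def write_consensus_tsv(calls: Sequence[MutationCall], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "position": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "locus": c.locus,
            "frequency": c.frequency,
            "callers": ",".join(sorted(c.callers)),
            "annotation": c.annotation,
            "line": c.line,
            "generation": c.generation,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_consensus_tsv(path: str | Path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "line": str})
    return [
        MutationCall(
            locus=str(r.locus),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            frequency=float(r.frequency),
            callers=frozenset(str(r.callers).split(",")),
            annotation=str(r.annotation),
            line="" if pd.isna(r.line) else str(r.line),
            generation=int(r.generation),
            chrom="" if pd.isna(r.chrom) else str(r.chrom),
        )
        for r in df.itertuples()
    ]
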