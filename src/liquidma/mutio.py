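"""Mutation tables: reading, validation, classification and spectra.

Base-pair substitutions (BPS) are collapsed by strand into the six canonical
classes used throughout bacterial mutation-accumulation work: a substitution
and its reverse complement are the same event on double-stranded DNA, so
A→G and T→C are both "A:T->G:C". Spectra are per-class counts and
frequencies over the BPS records of an experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import BASES, COMPLEMENT, CodingIndex, GeneAnnotation, Genome

__all__ = [
    "BPS_CLASSES",
    "MutationRecord",
    "SpectrumTable",
    "classify_bps",
    "read_mutation_table",
    "write_mutation_table",
    "records_to_frame",
    "frame_to_records",
    "annotate_mutations",
    "spectrum_counts",
    "exclude_lines",
]

#: The six strand-collapsed substitution classes, transitions first.
BPS_CLASSES = ("A:T->G:C", "G:C->A:T", "A:T->C:G",
               "A:T->T:A", "G:C->T:A", "G:C->C:G")

_PURINE_FORM = {
    ("A", "G"): "A:T->G:C",
    ("A", "C"): "A:T->C:G",
    ("A", "T"): "A:T->T:A",
    ("G", "A"): "G:C->A:T",
    ("G", "T"): "G:C->T:A",
    ("G", "C"): "G:C->C:G",
}


def classify_bps(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    A pyrimidine-reference substitution is complemented onto its purine
    representative first, so classify(T, C) == classify(A, G) == "A:T->G:C".
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ref/alt must be single ACGT bases, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    if ref in "TC":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return _PURINE_FORM[(ref, alt)]


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation in one MA line.

    ``bps_class`` is present exactly when the record is a substitution;
    ``genic`` and ``effect`` stay None until :func:`annotate_mutations`.
    """

    line_id: str
    position: int
    ref: str
    alt: str
    is_indel: bool = False
    bps_class: str | None = None
    genic: str | None = None     # "intragenic" | "intergenic"
    effect: str | None = None    # "synonymous" | "nonsynonymous" | "noncoding" | "disruptive"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position {self.position} must be 1-based (>= 1)")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref!r}) at position {self.position}")
        if not self.is_indel:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(
                    f"BPS record at {self.position} must have single-base ref/alt, "
                    f"got {self.ref!r}->{self.alt!r}"
                )
            expected = classify_bps(self.ref, self.alt)
            if self.bps_class is None:
                object.__setattr__(self, "bps_class", expected)
            elif self.bps_class != expected:
                raise ValueError(
                    f"bps_class {self.bps_class!r} inconsistent with {self.ref}->{self.alt}"
                )
        elif self.bps_class is not None:
            raise ValueError("indel records must not carry a bps_class")

    @property
    def indel_type(self) -> str | None:
        if not self.is_indel:
            return None
        return "INS" if len(self.alt) > len(self.ref) else "DEL"


@dataclass
class SpectrumTable:
    """Per-class BPS counts and frequencies for one treatment/experiment."""

    counts: dict[str, int]
    total: int = field(init=False)
    frequencies: dict[str, float] | None = field(init=False)

    def __post_init__(self) -> None:
        for cls in BPS_CLASSES:
            self.counts.setdefault(cls, 0)
        unknown = set(self.counts) - set(BPS_CLASSES)
        if unknown:
            raise ValueError(f"unknown BPS classes: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative class count")
        self.total = sum(self.counts.values())
        if self.total > 0:
            self.frequencies = {c: self.counts[c] / self.total for c in BPS_CLASSES}
        else:
            # flagged undefined rather than silently NaN
            self.frequencies = None

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "SpectrumTable":
        """Build from six counts ordered as :data:`BPS_CLASSES`."""
        if len(counts) != len(BPS_CLASSES):
            raise ValueError(f"expected {len(BPS_CLASSES)} counts, got {len(counts)}")
        return cls(dict(zip(BPS_CLASSES, (int(c) for c in counts))))

    def count(self, bps_class: str) -> int:
        return self.counts[bps_class]

    def frequency(self, bps_class: str) -> float:
        if self.frequencies is None:
            raise ValueError("spectrum has zero BPS records; frequencies undefined")
        return self.frequencies[bps_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bps_class": BPS_CLASSES,
            "count": [self.counts[c] for c in BPS_CLASSES],
            "frequency": [self.frequencies[c] if self.frequencies else float("nan")
                          for c in BPS_CLASSES],
        })


def spectrum_counts(records: Iterable[MutationRecord]) -> SpectrumTable:
    """Tally BPS records into the six classes; indels are excluded."""
    counts = {c: 0 for c in BPS_CLASSES}
    for rec in records:
        if rec.is_indel:
            continue
        counts[rec.bps_class] += 1
    return SpectrumTable(counts)


def exclude_lines(records: Iterable[MutationRecord],
                  line_ids: Sequence[str]) -> list[MutationRecord]:
    """Drop records from named lines (e.g. hypermutator exclusion)."""
    drop = set(line_ids)
    return [r for r in records if r.line_id not in drop]


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("line_id", "position", "ref", "alt", "type")
_OPTIONAL_COLUMNS = ("bps_class", "genic", "effect")


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "line_id": r.line_id,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "type": r.indel_type if r.is_indel else "BPS",
            "bps_class": r.bps_class or "",
            "genic": r.genic or "",
            "effect": r.effect or "",
        })
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS) + list(_OPTIONAL_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[MutationRecord]:
    missing = set(TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"mutation table missing required columns: {sorted(missing)}")
    records: list[MutationRecord] = []
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 2 = first data line
        try:
            rtype = str(row.type).upper()
            if rtype not in ("BPS", "INS", "DEL"):
                raise ValueError(f"unknown mutation type {row.type!r}")
            records.extend(_build_records(
                line_id=str(row.line_id),
                position=int(row.position),
                ref=str(row.ref).upper(),
                alt=str(row.alt).upper(),
                is_indel=rtype != "BPS",
                genic=(getattr(row, "genic", "") or None) or None,
                effect=(getattr(row, "effect", "") or None) or None,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise ValueError("malformed mutation table rows:\n  " + "\n  ".join(errors))
    return records


def _build_records(line_id: str, position: int, ref: str, alt: str,
                   is_indel: bool, genic=None, effect=None) -> list[MutationRecord]:
    if not is_indel and len(ref) == len(alt) and len(ref) > 1:
        # multi-nucleotide substitution: split into component single-base records
        warnings.warn(
            f"multi-nucleotide substitution {ref}->{alt} at {position} split into "
            f"{sum(a != b for a, b in zip(ref, alt))} single-base records",
            stacklevel=3,
        )
        return [
            MutationRecord(line_id, position + k, r, a, False, genic=genic, effect=effect)
            for k, (r, a) in enumerate(zip(ref, alt)) if r != a
        ]
    return [MutationRecord(line_id, position, ref, alt, is_indel,
                           genic=genic, effect=effect)]


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path, format: str = "tsv",
                        line_id: str | None = None,
                        genome: Genome | None = None) -> list[MutationRecord]:
    """Read mutation calls from TSV (declared schema) or minimal VCF 4.x.

    For VCF input, ``line_id`` labels all records (default: file stem);
    multi-allelic records are split. If a ``genome`` is supplied, positions
    are bounds-checked and offenders listed.
    """
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = frame_to_records(frame)
    elif format == "vcf":
        records = _read_vcf(path, line_id=line_id)
    else:
        raise ValueError(f"unknown mutation table format {format!r}")
    if genome is not None:
        out_of_bounds = [r for r in records if r.position > len(genome)]
        if out_of_bounds:
            offenders = ", ".join(str(r.position) for r in out_of_bounds[:10])
            raise ValueError(
                f"{len(out_of_bounds)} record(s) beyond genome length {len(genome)}: "
                f"positions {offenders}"
            )
    return records


def _read_vcf(path: str | Path, line_id: str | None = None) -> list[MutationRecord]:
    import pysam

    label = line_id if line_id is not None else Path(path).stem
    records: list[MutationRecord] = []
    contigs: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            contigs.add(rec.chrom)
            if len(contigs) > 1:
                raise ValueError(
                    f"VCF spans multiple contigs {sorted(contigs)}; a single "
                    "contig is assumed"
                )
            for alt in rec.alts or ():
                ref = rec.ref.upper()
                alt = alt.upper()
                is_indel = len(ref) != len(alt)
                records.extend(_build_records(label, rec.pos, ref, alt, is_indel))
    return records


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_mutations(records: Sequence[MutationRecord], genome: Genome,
                       annotation: GeneAnnotation,
                       genetic_code: int = 11) -> list[MutationRecord]:
    """Fill ``genic`` and ``effect`` for every record against a genome.

    Substitutions are classified by translating the owning codon before and
    after the change; coding indels are labeled "disruptive" (the
    nonsynonymous-equivalent category used in placement ratio tests) and
    noncoding indels "noncoding". The genome base must match ``ref`` for
    substitutions (the first base of ``ref`` for indels).
    """
    index = CodingIndex(genome, annotation, genetic_code=genetic_code)
    out: list[MutationRecord] = []
    for rec in records:
        if rec.position > len(genome):
            raise ValueError(f"record at {rec.position} beyond genome length {len(genome)}")
        genome_base = genome.base(rec.position)
        check = rec.ref[0]
        if genome_base != check:
            raise ValueError(
                f"ref mismatch for line {rec.line_id} at {rec.position}: "
                f"table says {check!r}, genome has {genome_base!r}"
            )
        intragenic = index.owner_of(rec.position) is not None
        genic = "intragenic" if intragenic else "intergenic"
        if rec.is_indel:
            effect = "disruptive" if intragenic else "noncoding"
        else:
            effect = index.effect_of(rec.position, rec.alt)
        out.append(replace(rec, genic=genic, effect=effect))
    return out
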