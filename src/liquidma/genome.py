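"""Genomes, CDS annotations, and composition-based null expectations.

A mutation-accumulation experiment tests for selection by comparing where
mutations land against where they *should* land if placement were neutral.
The null is set entirely by genome composition: the coding:noncoding ratio of
sites, and — within coding sequence — the ratio of effectively nonsynonymous
to effectively synonymous sites in the Nei–Gojobori sense (each coding
position contributes 1/3 of a site per possible substitution, classified by
whether the substitution preserves the encoded amino acid).

This module provides those composition counts for real genomes (FASTA + GFF3)
and for synthetic genomes generated with controlled GC content and coding
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "Gene",
    "GeneAnnotation",
    "SiteClassTable",
    "ExpectedRatios",
    "CodingIndex",
    "synthesize_genome",
    "count_site_classes",
    "expected_ratios",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "revcomp",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single chromosome/contig restricted to the ACGT alphabet."""

    sequence: str
    id: str = "genome"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(
                f"genome contains non-ACGT characters: {sorted(bad)!r} "
                "(degenerate bases are not supported)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside genome of length {len(self)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Gene:
    """One gene with 1-based inclusive coordinates.

    ``cds`` marks the feature as frame-defining protein-coding sequence;
    only CDS features participate in effect classification.
    """

    start: int
    end: int
    strand: str
    cds: bool = True
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene start {self.start} must be >= 1 (1-based coordinates)")
        if self.start > self.end:
            raise ValueError(f"gene start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds and (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"CDS length {self.end - self.start + 1} for gene "
                f"[{self.start}, {self.end}] is not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """Ordered list of genes; order resolves overlapping-CDS ownership."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def validate_against(self, genome: Genome) -> None:
        for g in self.genes:
            if g.end > len(genome):
                raise ValueError(
                    f"gene [{g.start}, {g.end}] extends past genome length {len(genome)}"
                )


@dataclass
class SiteClassTable:
    """Genome composition counts parameterizing the neutral-placement nulls.

    ``eff_nonsyn_sites``/``eff_syn_sites`` are real-valued Nei–Gojobori site
    counts: each coding position splits its 3 possible substitutions into
    thirds of a site by synonymy.
    """

    coding_sites: int
    noncoding_sites: int
    eff_nonsyn_sites: float
    eff_syn_sites: float
    at_sites: int
    gc_sites: int

    def __post_init__(self) -> None:
        for name in ("coding_sites", "noncoding_sites", "eff_nonsyn_sites",
                     "eff_syn_sites", "at_sites", "gc_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")
        if abs((self.eff_nonsyn_sites + self.eff_syn_sites) - self.coding_sites) > 1e-6:
            raise ValueError(
                "effective site counts do not sum to coding_sites: "
                f"{self.eff_nonsyn_sites} + {self.eff_syn_sites} != {self.coding_sites}"
            )

    @property
    def genome_length(self) -> int:
        return self.coding_sites + self.noncoding_sites

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("coding_sites\tnoncoding_sites\teff_nonsyn_sites\t"
                     "eff_syn_sites\tat_sites\tgc_sites\n")
            fh.write(f"{self.coding_sites}\t{self.noncoding_sites}\t"
                     f"{self.eff_nonsyn_sites:.6f}\t{self.eff_syn_sites:.6f}\t"
                     f"{self.at_sites}\t{self.gc_sites}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteClassTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            values = fh.readline().rstrip("\n").split("\t")
        rec = dict(zip(header, values))
        return cls(
            coding_sites=int(rec["coding_sites"]),
            noncoding_sites=int(rec["noncoding_sites"]),
            eff_nonsyn_sites=float(rec["eff_nonsyn_sites"]),
            eff_syn_sites=float(rec["eff_syn_sites"]),
            at_sites=int(rec["at_sites"]),
            gc_sites=int(rec["gc_sites"]),
        )


@dataclass(frozen=True)
class ExpectedRatios:
    """Neutral expectations implied by genome composition."""

    coding_noncoding: float
    nonsyn_syn: float

    def __post_init__(self) -> None:
        if self.coding_noncoding <= 0 or self.nonsyn_syn <= 0:
            raise ValueError("expected ratios must be positive")


def _codon_to_aa(genetic_code: int) -> dict[str, str]:
    # Stop codons are mapped to '*'; a substitution creating or destroying a
    # stop therefore classifies as nonsynonymous, while stop<->stop preserves.
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    aa = dict(table.forward_table)
    for codon in table.stop_codons:
        aa[codon] = "*"
    return aa


class CodingIndex:
    """Position -> owning CDS lookup with codon-level effect classification.

    A position covered by two or more CDS features is owned by the first gene
    in annotation order; all conflicts are reported in a single warning.
    CDSs with internal stop codons are warned about but still counted.
    """

    def __init__(self, genome: Genome, annotation: GeneAnnotation,
                 genetic_code: int = 11) -> None:
        annotation.validate_against(genome)
        self.genome = genome
        self.annotation = annotation
        self.genetic_code = genetic_code
        self.aa_of = _codon_to_aa(genetic_code)

        L = len(genome)
        self.owner = np.full(L, -1, dtype=np.int64)  # 0-based position -> gene index
        self._cds_seq: dict[int, str] = {}
        conflicts: list[int] = []
        internal_stops: list[int] = []

        for gi, gene in enumerate(annotation.genes):
            if not gene.cds:
                continue
            cds = genome.sequence[gene.start - 1:gene.end]
            if gene.strand == "-":
                cds = revcomp(cds)
            self._cds_seq[gi] = cds
            for ci in range(0, len(cds) - 3, 3):
                if self.aa_of[cds[ci:ci + 3]] == "*":
                    internal_stops.append(gi)
                    break
            for idx in range(len(cds)):
                gpos0 = (gene.start - 1 + idx) if gene.strand == "+" else (gene.end - 1 - idx)
                if self.owner[gpos0] != -1:
                    conflicts.append(gpos0 + 1)
                else:
                    self.owner[gpos0] = gi

        if internal_stops:
            warnings.warn(
                f"{len(internal_stops)} CDS feature(s) contain internal stop codons "
                f"(gene indices {internal_stops[:10]}); counted as-is.",
                stacklevel=2,
            )
        if conflicts:
            warnings.warn(
                f"{len(conflicts)} position(s) covered by overlapping CDS features; "
                f"each counted once for the first gene in annotation order "
                f"(first few positions: {sorted(set(conflicts))[:10]}).",
                stacklevel=2,
            )

    def owner_of(self, position: int) -> int | None:
        """Index of the CDS owning a 1-based position, or None if noncoding."""
        gi = int(self.owner[position - 1])
        return None if gi < 0 else gi

    def _codon_context(self, position: int, gi: int) -> tuple[str, int]:
        """(codon, offset-within-codon) for a 1-based position in gene gi."""
        gene = self.annotation.genes[gi]
        idx = (position - gene.start) if gene.strand == "+" else (gene.end - position)
        ci, off = divmod(idx, 3)
        cds = self._cds_seq[gi]
        return cds[3 * ci:3 * ci + 3], off

    def effect_of(self, position: int, alt: str) -> str:
        """Classify substituting the genome base at ``position`` by ``alt``.

        Returns "synonymous", "nonsynonymous" or "noncoding".
        """
        if alt not in BASES:
            raise ValueError(f"alt base {alt!r} not in ACGT")
        gi = self.owner_of(position)
        if gi is None:
            return "noncoding"
        gene = self.annotation.genes[gi]
        codon, off = self._codon_context(position, gi)
        cds_alt = alt if gene.strand == "+" else COMPLEMENT[alt]
        alt_codon = codon[:off] + cds_alt + codon[off + 1:]
        return "synonymous" if self.aa_of[alt_codon] == self.aa_of[codon] else "nonsynonymous"


def count_site_classes(genome: Genome, annotation: GeneAnnotation,
                       genetic_code: int = 11) -> SiteClassTable:
    """Tally genome composition into the classes that set the null ratios.

    Every coding position contributes 1/3 site per possible substitution to
    the effectively synonymous tally if the substitution preserves the amino
    acid, else to the effectively nonsynonymous tally. Noncoding positions
    contribute only to the coding/noncoding and AT/GC tallies.
    """
    index = CodingIndex(genome, annotation, genetic_code=genetic_code)
    eff_syn = 0.0
    eff_nonsyn = 0.0
    coding_positions = np.flatnonzero(index.owner >= 0)
    for gpos0 in coding_positions:
        position = int(gpos0) + 1
        base = genome.sequence[gpos0]
        for alt in BASES:
            if alt == base:
                continue
            if index.effect_of(position, alt) == "synonymous":
                eff_syn += 1.0 / 3.0
            else:
                eff_nonsyn += 1.0 / 3.0
    coding = int(coding_positions.size)
    # re-anchor the thirds so the conservation invariant holds to float precision
    if coding:
        total = eff_syn + eff_nonsyn
        eff_syn *= coding / total
        eff_nonsyn = coding - eff_syn
    at = genome.sequence.count("A") + genome.sequence.count("T")
    return SiteClassTable(
        coding_sites=coding,
        noncoding_sites=len(genome) - coding,
        eff_nonsyn_sites=eff_nonsyn,
        eff_syn_sites=eff_syn,
        at_sites=at,
        gc_sites=len(genome) - at,
    )


def expected_ratios(table: SiteClassTable) -> ExpectedRatios:
    """Neutral coding:noncoding and nonsynonymous:synonymous expectations."""
    if table.noncoding_sites <= 0:
        raise ZeroDivisionError("noncoding_sites must be positive to form a ratio")
    if table.eff_syn_sites <= 0:
        raise ZeroDivisionError("eff_syn_sites must be positive to form a ratio")
    return ExpectedRatios(
        coding_noncoding=table.coding_sites / table.noncoding_sites,
        nonsyn_syn=table.eff_nonsyn_sites / table.eff_syn_sites,
    )


# ---------------------------------------------------------------------------
# synthetic genome generation
# ---------------------------------------------------------------------------

_MIN_CODONS = 10  # smallest synthetic gene: start + 8 internal + stop


def synthesize_genome(length: int, gc_fraction: float = 0.5,
                      coding_fraction: float = 0.0, mean_gene_length: int = 900,
                      seed: int = 0, genetic_code: int = 11,
                      ) -> tuple[Genome, GeneAnnotation]:
    """Generate a random genome with non-overlapping CDS genes.

    Genes have exponentially distributed lengths (mean ``mean_gene_length``,
    floored at 30 bp, rounded to codons), start with ATG, end with a stop
    codon, carry iid internal sense codons at the requested GC content, and
    sit on a uniformly random strand. Deterministic for a fixed seed.
    """
    if length < 300:
        raise ValueError("genome length must be >= 300 bp")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if not 0 <= coding_fraction < 1:
        raise ValueError("coding_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    aa_of = _codon_to_aa(genetic_code)
    stops = sorted(c for c, a in aa_of.items() if a == "*")
    base_p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                       gc_fraction / 2, (1 - gc_fraction) / 2])
    base_arr = np.array(list(BASES))

    target = int(round(coding_fraction * length))
    gene_lens: list[int] = []
    if target > 0:
        if target < 3 * _MIN_CODONS:
            raise ValueError(
                f"coding_fraction {coding_fraction} requests {target} coding bp, "
                f"below the minimum gene size of {3 * _MIN_CODONS} bp"
            )
        budget = target
        while budget >= 3 * _MIN_CODONS:
            n_codons = max(_MIN_CODONS,
                           int(round(rng.exponential(mean_gene_length / 3.0))))
            glen = min(3 * n_codons, 3 * (budget // 3))
            gene_lens.append(glen)
            budget -= glen
        if sum(gene_lens) > length:
            raise ValueError(
                f"cannot pack {sum(gene_lens)} coding bp into a {length} bp genome "
                "(coding_fraction too high for mean_gene_length)"
            )

    def _random_bases(n: int) -> str:
        return "".join(base_arr[rng.choice(4, size=n, p=base_p)]) if n else ""

    def _random_cds(glen: int) -> str:
        n_internal = glen // 3 - 2
        codons = ["ATG"]
        for _ in range(n_internal):
            while True:
                codon = _random_bases(3)
                if aa_of[codon] != "*":
                    codons.append(codon)
                    break
        codons.append(stops[rng.integers(len(stops))])
        return "".join(codons)

    # scatter genes along the genome with multinomially distributed gaps
    free = length - sum(gene_lens)
    k = len(gene_lens)
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1))) if k else [length]

    parts: list[str] = []
    genes: list[Gene] = []
    cursor = 0
    for i, glen in enumerate(gene_lens):
        gap = int(gaps[i])
        parts.append(_random_bases(gap))
        cursor += gap
        cds = _random_cds(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        genes.append(Gene(start=cursor + 1, end=cursor + glen, strand=strand,
                          cds=True, id=f"gene{i + 1:04d}"))
        cursor += glen
    parts.append(_random_bases(length - cursor))

    genome = Genome("".join(parts), id=f"synthetic_seed{seed}")
    assert len(genome) == length
    return genome, GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, record_id: str | None = None) -> Genome:
    """Read a genome from FASTA; first record unless ``record_id`` is given."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return Genome(str(rec.seq).upper(), id=rec.id)
    raise ValueError(f"no FASTA record {record_id!r} found in {path}")


def write_fasta(genome: Genome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Read CDS features (only) from a GFF3 file, preserving file order."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for i, feat in enumerate(db.features_of_type("CDS")):
        gid = feat.attributes.get("ID", [f"cds{i + 1:04d}"])[0]
        genes.append(Gene(start=feat.start, end=feat.end, strand=feat.strand,
                          cds=True, id=gid))
    return GeneAnnotation(genes)


def write_gff3(annotation: GeneAnnotation, path: str | Path,
               seqid: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(annotation.genes):
            gid = g.id or f"cds{i + 1:04d}"
            fh.write(f"{seqid}\tliquidma\tCDS\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t0\tID={gid}\n")
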