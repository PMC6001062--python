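"""Variant filtering and gene/domain collapsing of cohort genotypes.

Builds :class:`~sorva.freqtable.BurdenTable` objects from a diploid cohort:
variants are classified by protein consequence, filtered on cohort minor
allele frequency, and collapsed per gene (or per protein-domain instance)
into per-individual carrier indicators or variant-carriage counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .freqtable import (
    STANDARD_MAF_GRID,
    BurdenTable,
    ConsequenceClass,
    CountingMode,
    FilterKey,
    Population,
    Zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "LOF_CONSEQUENCES",
    "PROTEIN_ALTERING_CONSEQUENCES",
    "DEFAULT_TERM_MAP",
    "classify_consequence",
    "consequence_in_class",
    "VariantRecord",
    "Individual",
    "GenotypeMatrix",
    "GeneModel",
    "DomainInterval",
    "compute_cohort_maf",
    "filter_variants",
    "collapse_by_gene",
    "collapse_by_domain",
    "build_all_tables",
    "read_cohort",
    "read_gene_models",
    "read_domains",
]

MISSING = -1  # sentinel dosage for uncalled genotypes


class Consequence(str, Enum):
    """Controlled vocabulary of protein consequences."""

    MISSENSE_OR_INFRAME = "MISSENSE_OR_INFRAME"
    SPLICE_SITE = "SPLICE_SITE"
    STOP_GAIN = "STOP_GAIN"
    FRAMESHIFT = "FRAMESHIFT"
    OTHER = "OTHER"


#: Potential loss-of-function: splice site (within 2 bp of a junction),
#: stop gain, frameshift.
LOF_CONSEQUENCES = frozenset(
    {Consequence.SPLICE_SITE, Consequence.STOP_GAIN, Consequence.FRAMESHIFT}
)
#: Protein-altering: LOF plus missense / in-frame indels.
PROTEIN_ALTERING_CONSEQUENCES = LOF_CONSEQUENCES | {Consequence.MISSENSE_OR_INFRAME}

# Mapping from common annotation terms (Sequence Ontology and shorthand) to the
# controlled vocabulary; extend or override via the term_map arguments.
DEFAULT_TERM_MAP: dict[str, Consequence] = {
    "missense_variant": Consequence.MISSENSE_OR_INFRAME,
    "missense": Consequence.MISSENSE_OR_INFRAME,
    "nonsynonymous": Consequence.MISSENSE_OR_INFRAME,
    "inframe_insertion": Consequence.MISSENSE_OR_INFRAME,
    "inframe_deletion": Consequence.MISSENSE_OR_INFRAME,
    "protein_altering_variant": Consequence.MISSENSE_OR_INFRAME,
    "stop_gained": Consequence.STOP_GAIN,
    "stop_gain": Consequence.STOP_GAIN,
    "nonsense": Consequence.STOP_GAIN,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift": Consequence.FRAMESHIFT,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_site": Consequence.SPLICE_SITE,
    "synonymous_variant": Consequence.OTHER,
    "synonymous": Consequence.OTHER,
    "intron_variant": Consequence.OTHER,
    "intergenic_variant": Consequence.OTHER,
    "5_prime_UTR_variant": Consequence.OTHER,
    "3_prime_UTR_variant": Consequence.OTHER,
}


def classify_consequence(
    raw: str,
    term_map: Mapping[str, Consequence] | None = None,
    strict: bool = True,
) -> Consequence:
    """Map a raw annotation term onto the controlled consequence vocabulary.

    Unknown terms raise when ``strict`` (the default); otherwise they are
    classified ``OTHER`` with a warning.
    """
    mapping = DEFAULT_TERM_MAP if term_map is None else term_map
    term = raw.strip()
    if term in mapping:
        return mapping[term]
    if term.lower() in mapping:
        return mapping[term.lower()]
    if strict:
        raise ValueError(f"unknown consequence term {raw!r}")
    warnings.warn(f"unknown consequence term {raw!r}; classifying as OTHER", stacklevel=2)
    return Consequence.OTHER


def consequence_in_class(csq: Consequence, cls: ConsequenceClass) -> bool:
    if cls is ConsequenceClass.LOF_ONLY:
        return csq in LOF_CONSEQUENCES
    return csq in PROTEIN_ALTERING_CONSEQUENCES


@dataclass
class VariantRecord:
    """One (decomposed, biallelic) annotated variant."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    consequence: Consequence
    gene_ids: frozenset[str] = frozenset()
    transcript_ids: frozenset[str] = frozenset()
    cohort_maf: float | None = None

    @property
    def is_x(self) -> bool:
        return self.chrom.removeprefix("chr") == "X"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class Individual:
    sample_id: str
    sex: str = "F"  # 'M' or 'F'; drives hemizygous X handling
    population: str = "ALL"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.sample_id}: sex must be 'M' or 'F'")


@dataclass
class GenotypeMatrix:
    """Diploid cohort calls: dosage matrix (variants x individuals).

    Dosages are alternate-allele counts in {0, 1, 2} with -1 for missing.
    Male X-chromosome calls are hemizygous: a single alternate allele is
    recoded to dosage 2 (it behaves as homozygous for zygosity purposes) but
    contributes only one allele to frequency denominators.
    """

    individuals: list[Individual]
    variants: list[VariantRecord]
    calls: np.ndarray  # int8, shape (n_variants, n_individuals)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.individuals)})"
            )
        male = self._male_mask()
        for vi, v in enumerate(self.variants):
            if v.is_x:
                bad = male & (self.calls[vi] == 1)
                if bad.any():
                    raise ValueError(
                        f"{v.key}: heterozygous male X call for "
                        f"{[self.individuals[i].sample_id for i in np.where(bad)[0]]}"
                    )

    def _male_mask(self) -> np.ndarray:
        return np.array([ind.sex == "M" for ind in self.individuals])

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def ploidy(self, variant_index: int) -> np.ndarray:
        """Per-individual allele count at a site (1 for male X, else 2)."""
        if self.variants[variant_index].is_x:
            return np.where(self._male_mask(), 1, 2)
        return np.full(self.n_individuals, 2)

    def population_mask(self, population: Population | str) -> np.ndarray:
        pop = population.value if isinstance(population, Population) else population
        if pop == "ALL":
            return np.ones(self.n_individuals, dtype=bool)
        return np.array([ind.population == pop for ind in self.individuals])

    def compute_mafs(self) -> None:
        """Fill ``cohort_maf`` for every variant from the full cohort."""
        for vi in range(len(self.variants)):
            self.variants[vi].cohort_maf = compute_cohort_maf(self, vi)

    def gene_index(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for vi, v in enumerate(self.variants):
            for g in v.gene_ids:
                idx.setdefault(g, []).append(vi)
        return idx


def compute_cohort_maf(matrix: GenotypeMatrix, variant_index: int) -> float:
    """Cohort minor allele frequency of a variant, folded to the rarer allele.

    Missing genotypes are excluded from the denominator; each called male X
    genotype contributes a single allele.
    """
    calls = matrix.calls[variant_index]
    called = calls != MISSING
    if not called.any():
        raise ValueError(f"{matrix.variants[variant_index].key}: all genotypes missing")
    ploidy = matrix.ploidy(variant_index)
    # hemizygous alt stored as dosage 2 = 1 alt allele on 1 chromosome
    alt = np.where(ploidy == 1, calls // 2, calls)
    alt_alleles = int(alt[called].sum())
    total_alleles = int(ploidy[called].sum())
    freq = alt_alleles / total_alleles
    return min(freq, 1.0 - freq)


def filter_variants(
    matrix: GenotypeMatrix,
    maf_threshold: float,
    consequence_class: ConsequenceClass,
) -> list[int]:
    """Indices of variants with cohort MAF strictly below the threshold and a
    consequence in the requested class."""
    keep = []
    for vi, v in enumerate(matrix.variants):
        if v.cohort_maf is None:
            v.cohort_maf = compute_cohort_maf(matrix, vi)
        if v.cohort_maf < maf_threshold and consequence_in_class(
            v.consequence, consequence_class
        ):
            keep.append(vi)
    return keep


def _carrier_counts(
    calls: np.ndarray, zygosity: Zygosity, mode: CountingMode
) -> int:
    """Collapse a (variants x individuals) dosage block into one count."""
    het = calls == 1
    hom = calls == 2
    if mode is CountingMode.BINARY_PER_INDIVIDUAL:
        if zygosity is Zygosity.HET:
            qualifies = het.any(axis=0)
        elif zygosity is Zygosity.HOM:
            qualifies = hom.any(axis=0)
        elif zygosity is Zygosity.BOTH:
            qualifies = (het | hom).any(axis=0)
        else:  # CHET_OR_HOM: >=1 hom site or >=2 distinct het sites
            qualifies = hom.any(axis=0) | (het.sum(axis=0) >= 2)
        return int(qualifies.sum())
    # VARIANT_MULTIPLICITY: one event per (variant, individual) with a
    # qualifying genotype of the requested zygosity
    if zygosity is Zygosity.HET:
        events = het
    elif zygosity is Zygosity.HOM:
        events = hom
    elif zygosity is Zygosity.BOTH:
        events = het | hom
    else:
        raise ValueError("CHET_OR_HOM is undefined in VARIANT_MULTIPLICITY mode")
    return int(events.sum())


def _make_key(
    population: Population,
    maf_threshold: float,
    consequence_class: ConsequenceClass,
    zygosity: Zygosity,
    mode: CountingMode,
) -> FilterKey:
    return FilterKey(
        population=population,
        maf_threshold=maf_threshold,
        consequence_class=consequence_class,
        zygosity=zygosity,
        mode=mode,
    )


def collapse_by_gene(
    matrix: GenotypeMatrix,
    qualifying: Sequence[int],
    zygosity: Zygosity,
    mode: CountingMode = CountingMode.BINARY_PER_INDIVIDUAL,
    population: Population = Population.ALL,
    key: FilterKey | None = None,
    feature_universe: Iterable[str] | None = None,
) -> BurdenTable:
    """Collapse qualifying variants per gene into a burden table.

    An individual counts for a gene if any qualifying variant mapping to any
    transcript of the gene meets the zygosity requirement (binary mode), or
    contributes one event per qualifying variant carried (multiplicity mode).
    ``feature_universe`` densifies the table over genes with zero carriers.
    """
    if zygosity is Zygosity.CHET_OR_HOM and mode is not CountingMode.BINARY_PER_INDIVIDUAL:
        raise ValueError("CHET_OR_HOM zygosity requires BINARY_PER_INDIVIDUAL mode")
    if key is None:
        key = _make_key(population, 1e-9, ConsequenceClass.PROTEIN_ALTERING, zygosity, mode)
    mask = matrix.population_mask(population)
    table = BurdenTable(key=key, cohort_size=int(mask.sum()))
    gene_to_vars: dict[str, list[int]] = {}
    for vi in qualifying:
        for g in matrix.variants[vi].gene_ids:
            gene_to_vars.setdefault(g, []).append(vi)
    universe = set(feature_universe) if feature_universe is not None else set(gene_to_vars)
    for gene in sorted(universe):
        vis = gene_to_vars.get(gene, [])
        if not vis:
            table.add(gene, 0)
            continue
        block = matrix.calls[np.ix_(np.asarray(vis), np.where(mask)[0])]
        table.add(gene, _carrier_counts(block, zygosity, mode))
    return table


def collapse_by_domain(
    matrix: GenotypeMatrix,
    qualifying: Sequence[int],
    domains: Sequence["DomainInterval"],
    zygosity: Zygosity,
    mode: CountingMode = CountingMode.BINARY_PER_INDIVIDUAL,
    population: Population = Population.ALL,
    key: FilterKey | None = None,
) -> BurdenTable:
    """As :func:`collapse_by_gene`, keyed by protein-domain instance.

    A variant belongs to a domain instance when its position falls inside one
    of the instance's genomic intervals.  Instances with no mapped intervals
    are skipped with a warning.
    """
    if key is None:
        key = _make_key(population, 1e-9, ConsequenceClass.PROTEIN_ALTERING, zygosity, mode)
    mask = matrix.population_mask(population)
    table = BurdenTable(key=key, cohort_size=int(mask.sum()))
    cols = np.where(mask)[0]
    for dom in domains:
        if not dom.intervals:
            warnings.warn(f"domain {dom.instance_id} has no mapped intervals; skipped")
            continue
        vis = [vi for vi in qualifying if dom.contains(matrix.variants[vi])]
        if not vis:
            table.add(dom.instance_id, 0)
            continue
        block = matrix.calls[np.ix_(np.asarray(vis), cols)]
        table.add(dom.instance_id, _carrier_counts(block, zygosity, mode))
    return table


def build_all_tables(
    matrix: GenotypeMatrix,
    domains: Sequence["DomainInterval"] | None = None,
    maf_thresholds: Sequence[float] = STANDARD_MAF_GRID,
    consequence_classes: Sequence[ConsequenceClass] = tuple(ConsequenceClass),
    zygosities: Sequence[Zygosity] = tuple(Zygosity),
    modes: Sequence[CountingMode] = (CountingMode.BINARY_PER_INDIVIDUAL,),
    populations: Sequence[Population] | None = None,
    per_population_maf: bool = False,
) -> dict[FilterKey, BurdenTable]:
    """Build burden tables over the full filtering grid, per population.

    MAF filtering uses frequencies computed on the full cohort even when
    collapsing a population subset (set ``per_population_maf`` to recompute
    frequencies within each subset instead).  Tables are dense over the union
    of gene identifiers seen in the variant annotations.
    """
    matrix.compute_mafs()
    if populations is None:
        labels = {ind.population for ind in matrix.individuals}
        populations = [Population.ALL] + [
            Population(p) for p in sorted(labels) if p in Population.__members__ and p != "ALL"
        ]
    universe = sorted({g for v in matrix.variants for g in v.gene_ids})
    global_mafs = [v.cohort_maf for v in matrix.variants]
    tables: dict[FilterKey, BurdenTable] = {}
    for pop in populations:
        if per_population_maf and pop is not Population.ALL:
            sub = subset_matrix(matrix, matrix.population_mask(pop))
            sub.compute_mafs()
            source = sub
        else:
            source = matrix
            for v, maf in zip(matrix.variants, global_mafs):
                v.cohort_maf = maf
        for maf in maf_thresholds:
            for cls in consequence_classes:
                qualifying = filter_variants(source, maf, cls)
                if source is not matrix:
                    # map subset indices back onto the full matrix
                    qual_keys = {source.variants[vi].key for vi in qualifying}
                    qualifying = [
                        vi for vi, v in enumerate(matrix.variants) if v.key in qual_keys
                    ]
                for mode in modes:
                    for zyg in zygosities:
                        if (
                            zyg is Zygosity.CHET_OR_HOM
                            and mode is not CountingMode.BINARY_PER_INDIVIDUAL
                        ):
                            continue
                        fkey = _make_key(pop, maf, cls, zyg, mode)
                        tables[fkey] = collapse_by_gene(
                            matrix,
                            qualifying,
                            zyg,
                            mode,
                            population=pop,
                            key=fkey,
                            feature_universe=universe,
                        )
                        logger.debug(
                            "built %s: %d features", fkey, len(tables[fkey])
                        )
    return tables


def subset_matrix(matrix: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    """A new matrix restricted to the individuals selected by ``mask``."""
    from dataclasses import replace

    individuals = [ind for ind, keep in zip(matrix.individuals, mask) if keep]
    variants = [replace(v, cohort_maf=None) for v in matrix.variants]
    return GenotypeMatrix(individuals, variants, matrix.calls[:, mask].copy())


# ---------------------------------------------------------------------------
# Gene models and protein-domain intervals


@dataclass
class GeneModel:
    """Transcript structure of one gene (0-based half-open exon intervals)."""

    gene_id: str
    exons: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    strand: str = "+"

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.exons)

    def transcript_length(self, transcript_id: str) -> int:
        """Spliced transcript length l_tx in nucleotide bases."""
        exons = self.exons[transcript_id]
        length = sum(end - start for _, start, end in exons)
        if length <= 0:
            raise ValueError(f"{self.gene_id}/{transcript_id}: non-positive length")
        return length


@dataclass
class DomainInterval:
    """One protein-domain instance mapped onto genomic coordinates."""

    instance_id: str
    domain_type_id: str
    gene_id: str
    transcript_id: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)  # 0-based half-open

    @property
    def length(self) -> int:
        """Domain length L_dom in bases of overlapped transcript."""
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, variant: VariantRecord) -> bool:
        pos0 = variant.pos - 1
        return any(
            variant.chrom == chrom and start <= pos0 < end
            for chrom, start, end in self.intervals
        )


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a BED-like TSV.

    Columns: chrom, start, end, gene_id, transcript_id[, strand]; one row per
    exon, coordinates 0-based half-open.  Lines starting with '#' are skipped.
    """
    models: dict[str, GeneModel] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: expected >=5 columns, got {line!r}")
            chrom, start, end, gene_id, tid = fields[:5]
            strand = fields[5] if len(fields) > 5 else "+"
            model = models.setdefault(gene_id, GeneModel(gene_id, strand=strand))
            model.exons.setdefault(tid, []).append((chrom, int(start), int(end)))
    for model in models.values():
        for tid, exons in model.exons.items():
            exons.sort(key=lambda e: (e[0], e[1]))
            for (c1, s1, e1), (c2, s2, e2) in zip(exons, exons[1:]):
                if c1 == c2 and s2 < e1:
                    raise ValueError(
                        f"{model.gene_id}/{tid}: overlapping exons "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
    return models


def read_domains(path: str | Path) -> list[DomainInterval]:
    """Read domain instances from TSV.

    Columns: instance_id, domain_type_id, gene_id, transcript_id, chrom,
    start, end; one row per genomic interval, 0-based half-open.
    """
    by_id: dict[str, DomainInterval] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: expected 7 columns, got {line!r}")
            iid, dtype, gene, tid, chrom, start, end = fields[:7]
            dom = by_id.setdefault(iid, DomainInterval(iid, dtype, gene, tid))
            dom.intervals.append((chrom, int(start), int(end)))
    return list(by_id.values())


# ---------------------------------------------------------------------------
# Cohort input: VCF + annotation sidecar (+ optional sample metadata)


def read_cohort(
    vcf_path: str | Path,
    annotations_path: str | Path,
    samples_path: str | Path | None = None,
    term_map: Mapping[str, Consequence] | None = None,
    strict: bool = True,
) -> GenotypeMatrix:
    """Load a cohort from a VCF plus a consequence-annotation sidecar.

    The sidecar TSV has columns: chrom, pos, ref, alt, consequence_term,
    gene_ids (semicolon-separated), transcript_ids (semicolon-separated).
    Only annotated variants are retained.  Multi-allelic VCF records are
    decomposed into biallelic records before annotation lookup.  The optional
    samples TSV (sample_id, sex, population) supplies sex for hemizygous-X
    recoding and population labels; unlisted samples default to female, 'ALL'.
    """
    annotations: dict[str, tuple[Consequence, frozenset[str], frozenset[str]]] = {}
    with open(annotations_path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{annotations_path}: expected 7 columns, got {line!r}")
            chrom, pos, ref, alt, term, genes, txs = fields[:7]
            annotations[f"{chrom}:{pos}:{ref}:{alt}"] = (
                classify_consequence(term, term_map, strict),
                frozenset(g for g in genes.split(";") if g),
                frozenset(t for t in txs.split(";") if t),
            )

    meta: dict[str, tuple[str, str]] = {}
    if samples_path is not None:
        with open(samples_path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                sid, sex, pop = line.rstrip("\n").split("\t")[:3]
                meta[sid] = (sex, pop)

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_ids = list(vcf.header.samples)
        individuals = [
            Individual(sid, *(meta.get(sid, ("F", "ALL")))) for sid in sample_ids
        ]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                vkey = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                ann = annotations.get(vkey)
                if ann is None:
                    continue
                csq, genes, txs = ann
                variant = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    consequence=csq,
                    gene_ids=genes,
                    transcript_ids=txs,
                )
                dosages = np.full(len(sample_ids), MISSING, dtype=np.int8)
                is_x = variant.is_x
                for si, sid in enumerate(sample_ids):
                    gt = rec.samples[sid].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    dose = sum(1 for a in gt if a == ai)
                    if is_x and len(gt) == 1:
                        dose *= 2  # hemizygous alt behaves as homozygous
                    dosages[si] = dose
                variants.append(variant)
                rows.append(dosages)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(individuals)), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, variants, calls)
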