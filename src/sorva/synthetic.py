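"""Synthetic cohorts, family studies and domain placements for testing.

The generators plant known parameters — per-gene carrier probabilities,
per-unit sharing probabilities, uniform variant placement — and emit the
exact truth alongside the data, so collapsing and significance code can be
checked against analytic values and Monte-Carlo oracles without any external
download.  Genotypes are drawn independently per variant (no linkage
disequilibrium): the collapsing and binomial calculus under test never use
LD, so the simplification costs nothing while keeping every planted truth
exact.  All outputs are deterministic functions of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .significance import (
    FamilialUnit,
    StudyDesign,
    UnitKind,
    ZygosityModel,
)

__all__ = [
    "SiteSpec",
    "GeneSpec",
    "CohortSpec",
    "CohortPaths",
    "simulate_cohort",
    "FamilyStudySpec",
    "simulate_family_study",
    "DomainPlacement",
    "simulate_domain_placement",
]


@dataclass(frozen=True)
class SiteSpec:
    """Planted genotype distribution at one variant site.

    ``p_het``/``p_hom`` are per-individual genotype probabilities (for a male
    at an X site the alternate-allele probability is their sum and the call
    is hemizygous).
    """

    p_het: float
    p_hom: float = 0.0
    consequence: str = "missense_variant"

    def __post_init__(self) -> None:
        if self.p_het < 0 or self.p_hom < 0 or self.p_het + self.p_hom > 1:
            raise ValueError(f"invalid genotype probabilities {self.p_het}, {self.p_hom}")


@dataclass
class GeneSpec:
    """One synthetic gene: a run of independent variant sites on a chromosome."""

    gene_id: str
    sites: list[SiteSpec]
    chrom: str = "1"
    start: int = 1000
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_id:
            self.transcript_id = f"{self.gene_id}.t1"

    # Exact per-individual carrier probabilities implied by the planted sites.

    def carrier_probabilities(self, sex: str = "F", x_chrom: bool | None = None) -> dict[str, float]:
        """Analytic carrier probability per zygosity channel for one individual."""
        is_x = self.chrom.removeprefix("chr") == "X" if x_chrom is None else x_chrom
        het = np.array([s.p_het for s in self.sites])
        hom = np.array([s.p_hom for s in self.sites])
        if is_x and sex == "M":
            alt = het + hom
            p_any = 1.0 - np.prod(1.0 - alt)
            return {"HET": 0.0, "HOM": p_any, "BOTH": p_any, "CHET_OR_HOM": p_any}
        p_het_any = 1.0 - np.prod(1.0 - het)
        p_hom_any = 1.0 - np.prod(1.0 - hom)
        none = 1.0 - het - hom
        p_both = 1.0 - np.prod(none)
        # qualify as CHet/Hom: >=1 hom site, or >=2 het sites
        q0 = np.prod(none)
        q1 = sum(
            het[i] * np.prod(np.delete(none, i)) for i in range(len(self.sites))
        )
        return {
            "HET": float(p_het_any),
            "HOM": float(p_hom_any),
            "BOTH": float(p_both),
            "CHET_OR_HOM": float(1.0 - q0 - q1),
        }


@dataclass
class CohortSpec:
    """Specification of a synthetic diploid cohort."""

    n_individuals: int
    genes: list[GeneSpec]
    male_fraction: float = 0.5
    populations: dict[str, float] = field(default_factory=lambda: {"ALL": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.populations and abs(sum(self.populations.values()) - 1.0) > 1e-9:
            raise ValueError("population proportions must sum to 1")
        for gene in self.genes:
            if not gene.sites:
                raise ValueError(
                    f"{gene.gene_id}: a gene with no variant sites cannot carry "
                    "a planted carrier probability"
                )


@dataclass(frozen=True)
class CohortPaths:
    vcf: Path
    annotations: Path
    samples: Path
    truth: Path


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortPaths:
    """Generate a synthetic cohort: VCF, annotation sidecar, samples, truth.

    Output files (all plain text, deterministic under ``spec.seed``):

    * ``cohort.vcf`` — diploid genotypes; hemizygous (haploid) male calls on X
    * ``annotations.tsv`` — variant key -> consequence term, gene, transcript
    * ``samples.tsv`` — sample_id, sex, population
    * ``truth.tsv`` — per gene, the exact population-average carrier
      probability per zygosity channel (sex-weighted for X genes)
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals

    sample_ids = [f"S{i:05d}" for i in range(n)]
    sexes = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    pops = list(spec.populations)
    probs = np.array([spec.populations[p] for p in pops])
    pop_labels = (
        rng.choice(pops, size=n, p=probs) if n else np.array([], dtype=object)
    )

    samples_path = out_dir / "samples.tsv"
    with open(samples_path, "w", encoding="utf-8") as fh:
        fh.write("#sample_id\tsex\tpopulation\n")
        for sid, sex, pop in zip(sample_ids, sexes, pop_labels):
            fh.write(f"{sid}\t{sex}\t{pop}\n")

    chroms = []
    for gene in spec.genes:
        if gene.chrom not in chroms:
            chroms.append(gene.chrom)

    vcf_path = out_dir / "cohort.vcf"
    ann_path = out_dir / "annotations.tsv"
    with open(vcf_path, "w", encoding="utf-8") as vf, open(
        ann_path, "w", encoding="utf-8"
    ) as af:
        vf.write("##fileformat=VCFv4.2\n")
        vf.write("##source=sorva-synthetic\n")
        for chrom in chroms:
            vf.write(f"##contig=<ID={chrom}>\n")
        vf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            header_cols += ["FORMAT", *sample_ids]
        vf.write("\t".join(header_cols) + "\n")
        af.write("#chrom\tpos\tref\talt\tconsequence\tgene_ids\ttranscript_ids\n")
        male = sexes == "M"
        for gene in spec.genes:
            is_x = gene.chrom.removeprefix("chr") == "X"
            for si, site in enumerate(gene.sites):
                pos = gene.start + 10 * si
                u = rng.random(n)
                # diploid draw: hom if u < p_hom, het if u < p_hom + p_het
                dose = np.where(u < site.p_hom, 2, np.where(u < site.p_hom + site.p_het, 1, 0))
                gts = []
                for ii in range(n):
                    if is_x and male[ii]:
                        # hemizygous: alt with probability p_het + p_hom
                        gts.append("1" if u[ii] < site.p_hom + site.p_het else "0")
                    else:
                        gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(dose[ii])])
                row = [gene.chrom, str(pos), ".", "A", "G", ".", "PASS", "."]
                if gts:
                    row += ["GT", *gts]
                vf.write("\t".join(row) + "\n")
                af.write(
                    f"{gene.chrom}\t{pos}\tA\tG\t{site.consequence}\t"
                    f"{gene.gene_id}\t{gene.transcript_id}\n"
                )

    truth_path = out_dir / "truth.tsv"
    male_frac = spec.male_fraction
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tp_het\tp_hom\tp_both\tp_chet_or_hom\n")
        for gene in spec.genes:
            female = gene.carrier_probabilities("F")
            is_x = gene.chrom.removeprefix("chr") == "X"
            if is_x:
                male_p = gene.carrier_probabilities("M")
                avg = {
                    z: (1 - male_frac) * female[z] + male_frac * male_p[z]
                    for z in female
                }
            else:
                avg = female
            fh.write(
                f"{gene.gene_id}\t{avg['HET']:.10g}\t{avg['HOM']:.10g}"
                f"\t{avg['BOTH']:.10g}\t{avg['CHET_OR_HOM']:.10g}\n"
            )

    return CohortPaths(vcf_path, ann_path, samples_path, truth_path)


@dataclass
class FamilyStudySpec:
    """Specification of a synthetic family study.

    ``enrichment`` multiplies the per-unit chance success probability: 1
    simulates the null (no association), 0 never produces a success, larger
    values emulate a causal gene.
    """

    n_singletons: int = 0
    n_sib_pairs: int = 0
    n_consanguineous: int = 0
    consanguineous_E: int = 5
    n_shared_het_groups: int = 0
    shared_het_size: int = 3
    enrichment: float = 1.0
    zygosity_model: ZygosityModel = ZygosityModel.HET_SHARING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment multiplier must be >= 0")


def _unit_probability(
    kind: UnitKind, f: float, spec: FamilyStudySpec
) -> float:
    if kind is UnitKind.SINGLETON:
        p = f
    elif kind is UnitKind.SIB_PAIR:
        p = 0.25 * f if spec.zygosity_model is ZygosityModel.HOM_SHARING else 0.5 * f
    elif kind is UnitKind.CONSANGUINEOUS_PAIR:
        p = f * 0.5 ** (spec.consanguineous_E - 1)
    else:
        p = f * 0.5 ** (spec.shared_het_size - 1)
    return min(1.0, p * spec.enrichment)


def simulate_family_study(
    spec: FamilyStudySpec,
    f: float,
    rng: np.random.Generator | None = None,
) -> StudyDesign:
    """Draw unit successes under the planted sharing model.

    Each unit succeeds independently with the chance probability appropriate
    to its kind (singleton f, sib pair r*f or f/4, consanguineous pair
    f*(1/2)**(E-1), s-member group f*(1/2)**(s-1)), scaled by the enrichment
    multiplier.  Returns a :class:`StudyDesign` ready for evaluation.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"f must be in [0, 1], got {f}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    units: list[FamilialUnit] = []
    for kind, count, kwargs in (
        (UnitKind.SINGLETON, spec.n_singletons, {}),
        (UnitKind.SIB_PAIR, spec.n_sib_pairs, {"size": 2}),
        (
            UnitKind.CONSANGUINEOUS_PAIR,
            spec.n_consanguineous,
            {"size": 2, "E": spec.consanguineous_E},
        ),
        (
            UnitKind.SHARED_HET_GROUP,
            spec.n_shared_het_groups,
            {"size": spec.shared_het_size},
        ),
    ):
        p = _unit_probability(kind, f, spec)
        if count:
            successes = rng.random(count) < p
            units.extend(
                FamilialUnit(kind, success=bool(s), **kwargs) for s in successes
            )
    return StudyDesign(units, zygosity_model=spec.zygosity_model)


@dataclass
class DomainPlacement:
    """Null distribution of domain variant counts under uniform placement."""

    counts: np.ndarray  # per-replicate variants landing in the domain
    scores: np.ndarray  # per-replicate depletion scores
    V: int
    length_share: float

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())

    def empirical_pvalue(self, v_obs: int) -> float:
        """Empirical lower-tail probability P(count <= v_obs)."""
        return float((self.counts <= v_obs).mean())


def simulate_domain_placement(
    V: int,
    l_tx: int,
    domain_intervals: list[tuple[int, int]],
    replicates: int = 10_000,
    seed: int = 0,
) -> DomainPlacement:
    """Place V variants uniformly along a transcript, repeatedly.

    ``domain_intervals`` are half-open intervals in transcript coordinates
    [0, l_tx).  Returns per-replicate counts of variants landing in the
    domain and the corresponding depletion scores, for comparison against
    the binomial depletion P-value.
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    L_dom = sum(end - start for start, end in domain_intervals)
    if not 0 < L_dom <= l_tx:
        raise ValueError("domain intervals must be non-empty and within the transcript")
    rng = np.random.default_rng(seed)
    in_domain = np.zeros(l_tx, dtype=bool)
    for start, end in domain_intervals:
        in_domain[start:end] = True
    sites = rng.integers(0, l_tx, size=(replicates, V))
    counts = in_domain[sites].sum(axis=1)
    length_share = L_dom / l_tx
    scores = (counts / V) / length_share
    return DomainPlacement(counts=counts, scores=scores, V=V, length_share=length_share)
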