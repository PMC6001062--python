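"""Mutational-burden frequency tables.

A burden table records, for one combination of filtering thresholds, how many
individuals in a reference cohort carry a qualifying rare variant in each gene
(or protein-domain instance).  The fraction ``count / cohort_size`` is the
a-priori probability *f* that a random individual carries such a variant, the
basic ingredient of every significance calculation in :mod:`sorva.significance`
and of the predictive-genomics calculations in :mod:`sorva.predictive`.

The reference cohort emulated throughout is a 2504-individual population
panel spanning five continental superpopulations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Population",
    "ConsequenceClass",
    "Zygosity",
    "CountingMode",
    "STANDARD_MAF_GRID",
    "FilterKey",
    "BurdenRecord",
    "BurdenTable",
    "PopulationDivergence",
    "query_fraction",
    "zero_count_substitute",
    "rank_genes",
    "population_divergence",
    "read_table",
    "write_table",
]


class Population(str, Enum):
    """Cohort grouping: the aggregate panel or one continental superpopulation."""

    ALL = "ALL"
    AFR = "AFR"
    AMR = "AMR"
    EAS = "EAS"
    EUR = "EUR"
    SAS = "SAS"


class ConsequenceClass(str, Enum):
    """Variant-consequence filter applied before collapsing.

    ``LOF_ONLY`` keeps splice-site (within 2 bp of a junction), stop-gain and
    frameshift variants; ``PROTEIN_ALTERING`` additionally keeps missense and
    in-frame indel changes.
    """

    PROTEIN_ALTERING = "PROTEIN_ALTERING"
    LOF_ONLY = "LOF_ONLY"


class Zygosity(str, Enum):
    """Genotype requirement for an individual to count as a carrier.

    ``CHET_OR_HOM`` qualifies an individual who is homozygous for one
    qualifying variant or carries two or more qualifying heterozygous variants
    in the feature (a phase-unaware compound-heterozygote surrogate).
    """

    HET = "HET"
    HOM = "HOM"
    BOTH = "BOTH"
    CHET_OR_HOM = "CHET_OR_HOM"


class CountingMode(str, Enum):
    """Whether collapsing counts carriers or variant-carriage events.

    ``BINARY_PER_INDIVIDUAL`` counts each individual at most once per feature;
    ``VARIANT_MULTIPLICITY`` counts an individual once per qualifying variant
    they carry (an individual with two rare variants in a gene counts twice).
    """

    BINARY_PER_INDIVIDUAL = "BINARY_PER_INDIVIDUAL"
    VARIANT_MULTIPLICITY = "VARIANT_MULTIPLICITY"


#: The five MAF thresholds of the standard filtering grid (5%, 1%, 0.5%, 0.1%, 0.05%).
STANDARD_MAF_GRID: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001, 0.0005)


@dataclass(frozen=True)
class FilterKey:
    """The full filtering scenario a burden table was built under."""

    population: Population = Population.ALL
    maf_threshold: float = 0.001
    consequence_class: ConsequenceClass = ConsequenceClass.PROTEIN_ALTERING
    zygosity: Zygosity = Zygosity.BOTH
    mode: CountingMode = CountingMode.BINARY_PER_INDIVIDUAL

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold <= 0.5:
            raise ValueError(f"maf_threshold must be in (0, 0.5], got {self.maf_threshold}")
        if (
            self.zygosity is Zygosity.CHET_OR_HOM
            and self.mode is not CountingMode.BINARY_PER_INDIVIDUAL
        ):
            raise ValueError("CHET_OR_HOM zygosity requires BINARY_PER_INDIVIDUAL mode")


@dataclass(frozen=True)
class BurdenRecord:
    """Carrier (or carriage-event) count for one feature."""

    feature_id: str
    count: int
    cohort_size: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.feature_id}: negative count {self.count}")
        if self.cohort_size <= 0:
            raise ValueError(f"{self.feature_id}: cohort_size must be positive")

    @property
    def fraction(self) -> float:
        return self.count / self.cohort_size


@dataclass
class BurdenTable:
    """A burden table: one :class:`FilterKey` plus per-feature counts.

    Absent features mean zero carriers: the table is dense over the annotated
    feature universe at build time, so a feature that never appears simply had
    no qualifying variant in the cohort.
    """

    key: FilterKey
    records: dict[str, BurdenRecord] = field(default_factory=dict)
    cohort_size: int = 2504
    provenance: str = ""

    def __post_init__(self) -> None:
        for rec in self.records.values():
            self._check_record(rec)

    def _check_record(self, rec: BurdenRecord) -> None:
        if rec.cohort_size != self.cohort_size:
            raise ValueError(
                f"{rec.feature_id}: record cohort_size {rec.cohort_size} != "
                f"table cohort_size {self.cohort_size}"
            )
        if (
            self.key.mode is CountingMode.BINARY_PER_INDIVIDUAL
            and rec.count > rec.cohort_size
        ):
            raise ValueError(
                f"{rec.feature_id}: count {rec.count} exceeds cohort size "
                f"{rec.cohort_size} in binary mode"
            )

    def add(self, feature_id: str, count: int) -> None:
        rec = BurdenRecord(feature_id, count, self.cohort_size)
        self._check_record(rec)
        self.records[feature_id] = rec

    def count(self, feature_id: str) -> int:
        """Carrier count for a feature; absent features have zero carriers."""
        rec = self.records.get(feature_id)
        return 0 if rec is None else rec.count

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.records

    def features(self) -> list[str]:
        return sorted(self.records)


class PopulationDivergence:
    """Per-population carrier fractions for one feature and their spread."""

    def __init__(
        self,
        fractions: dict[Population, float],
        variance: float,
        most_divergent: list[Population],
    ) -> None:
        self.fractions = fractions
        self.variance = variance
        self.most_divergent = most_divergent

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PopulationDivergence(variance={self.variance:.3g}, "
            f"most_divergent={[p.value for p in self.most_divergent]})"
        )


def query_fraction(table: BurdenTable, feature_id: str) -> float:
    """Fraction of cohort individuals carrying a qualifying variant in a feature.

    Parameters
    ----------
    table
        A burden table in ``BINARY_PER_INDIVIDUAL`` mode.
    feature_id
        Gene or domain-instance identifier.  A feature absent from the table
        is treated as having zero carriers (with a warning, since it may also
        indicate an identifier outside the annotated universe).

    Returns
    -------
    float
        ``count / cohort_size`` in [0, 1].
    """
    if table.key.mode is not CountingMode.BINARY_PER_INDIVIDUAL:
        raise ValueError(
            "fractions of individuals are undefined for a VARIANT_MULTIPLICITY "
            "table; rebuild in BINARY_PER_INDIVIDUAL mode"
        )
    rec = table.records.get(feature_id)
    if rec is None:
        warnings.warn(
            f"feature {feature_id!r} not in table; reporting zero carriers",
            stacklevel=2,
        )
        return 0.0
    return rec.fraction


def zero_count_substitute(count: int, cohort_size: int) -> float:
    """Carrier fraction with the zero-count substitution ``1/(2N)``.

    A gene with no observed carriers in a finite reference cohort does not
    have a carrier frequency of exactly zero; substituting ``1/(2N)`` (half an
    individual in a cohort of N) keeps downstream significance tests finite
    while remaining conservative.  Nonzero counts pass through as ``count/N``.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if count > 0:
        return count / cohort_size
    return 1.0 / (2 * cohort_size)


def rank_genes(tables: Sequence[BurdenTable]) -> dict[str, float]:
    """Rank features by mutation intolerance, low carrier count = better rank.

    The first table is the primary sort key (conventionally rare LOF carriers,
    MAF < 0.5%, either zygosity); later tables break ties in order
    (conventionally rare protein-altering, then less-rare protein-altering).
    Features still tied after all tie-breakers share a midrank.

    Returns a mapping feature_id -> rank (1 = most intolerant).
    """
    if not tables:
        raise ValueError("at least one table required")
    sizes = {t.cohort_size for t in tables}
    if len(sizes) != 1:
        raise ValueError(f"tables disagree on cohort_size: {sorted(sizes)}")
    universes = [frozenset(t.records) for t in tables]
    if len(set(universes)) != 1:
        raise ValueError("tables disagree on feature universe")
    features = tables[0].features()
    keys = [tuple(t.count(g) for t in tables) for g in features]
    order = {k: i for i, k in enumerate(sorted(set(keys)))}
    ranks = rankdata([order[k] for k in keys], method="average")
    return dict(zip(features, ranks.tolist()))


def population_divergence(
    tables: Mapping[Population, BurdenTable], feature_id: str
) -> PopulationDivergence:
    """Per-superpopulation carrier fractions, their variance, and the outlier.

    All five superpopulation tables must be present and share the filter key
    except for the population field.  The most divergent population is the one
    whose fraction deviates most (absolute deviation) from the mean across the
    five; exact ties are all reported, and a zero-variance feature has none.
    """
    wanted = [p for p in Population if p is not Population.ALL]
    missing = [p.value for p in wanted if p not in tables]
    if missing:
        raise ValueError(f"missing population tables: {missing}")
    base = {
        replace(t.key, population=Population.ALL) for p, t in tables.items() if p in wanted
    }
    if len(base) != 1:
        raise ValueError("population tables disagree on filter key")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fracs = {p: query_fraction(tables[p], feature_id) for p in wanted}
    values = np.array([fracs[p] for p in wanted])
    variance = float(np.var(values))
    if variance == 0.0:
        divergent: list[Population] = []
    else:
        dev = np.abs(values - values.mean())
        divergent = [p for p, d in zip(wanted, dev) if np.isclose(d, dev.max())]
    return PopulationDivergence(fracs, variance, divergent)


# ---------------------------------------------------------------------------
# Serialization: TSV with a '##' header block, plus a JSON mirror.

_HEADER_PREFIX = "##sorva-table"


def write_table(table: BurdenTable, path: str | Path) -> None:
    """Write a burden table as TSV (or JSON when the path ends in .json)."""
    path = Path(path)
    if path.suffix == ".json":
        _write_json(table, path)
        return
    k = table.key
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"{_HEADER_PREFIX}\tpopulation={k.population.value}"
            f"\tmaf_threshold={k.maf_threshold!r}"
            f"\tconsequence_class={k.consequence_class.value}"
            f"\tzygosity={k.zygosity.value}\tmode={k.mode.value}"
            f"\tcohort_size={table.cohort_size}\n"
        )
        if table.provenance:
            fh.write(f"##provenance\t{table.provenance}\n")
        fh.write("feature_id\tcount\tcohort_size\n")
        for fid in table.features():
            rec = table.records[fid]
            fh.write(f"{fid}\t{rec.count}\t{rec.cohort_size}\n")


def read_table(path: str | Path) -> BurdenTable:
    """Read a burden table written by :func:`write_table` (TSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        return _read_json(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_HEADER_PREFIX):
        raise ValueError(f"{path}: missing burden-table header line")
    meta: dict[str, str] = {}
    provenance = ""
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##provenance"):
            provenance = line.split("\t", 1)[1] if "\t" in line else ""
        elif line.startswith(_HEADER_PREFIX):
            for tok in line.split("\t")[1:]:
                key, _, val = tok.partition("=")
                meta[key] = val
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body_start = i
            break
    else:
        body_start = len(lines)
    try:
        key = FilterKey(
            population=Population(meta["population"]),
            maf_threshold=float(meta["maf_threshold"]),
            consequence_class=ConsequenceClass(meta["consequence_class"]),
            zygosity=Zygosity(meta["zygosity"]),
            mode=CountingMode(meta["mode"]),
        )
        cohort_size = int(meta["cohort_size"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed header: {exc}") from exc
    table = BurdenTable(key=key, cohort_size=cohort_size, provenance=provenance)
    body = lines[body_start:]
    if body and body[0].startswith("feature_id"):
        body = body[1:]
    for line in body:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}: malformed record line {line!r}")
        fid, count_s, n_s = fields
        count, n = int(count_s), int(n_s)
        if n != cohort_size:
            raise ValueError(f"{path}: record {fid} cohort_size {n} != header {cohort_size}")
        table.add(fid, count)
    return table


def _write_json(table: BurdenTable, path: Path) -> None:
    k = table.key
    payload = {
        "key": {
            "population": k.population.value,
            "maf_threshold": k.maf_threshold,
            "consequence_class": k.consequence_class.value,
            "zygosity": k.zygosity.value,
            "mode": k.mode.value,
        },
        "cohort_size": table.cohort_size,
        "provenance": table.provenance,
        "records": {fid: table.records[fid].count for fid in table.features()},
    }
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _read_json(path: Path) -> BurdenTable:
    payload = json.loads(path.read_text(encoding="utf-8"))
    k = payload["key"]
    key = FilterKey(
        population=Population(k["population"]),
        maf_threshold=float(k["maf_threshold"]),
        consequence_class=ConsequenceClass(k["consequence_class"]),
        zygosity=Zygosity(k["zygosity"]),
        mode=CountingMode(k["mode"]),
    )
    table = BurdenTable(
        key=key,
        cohort_size=int(payload["cohort_size"]),
        provenance=payload.get("provenance", ""),
    )
    for fid, count in payload["records"].items():
        table.add(fid, int(count))
    return table
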