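"""Binomial significance calculus for rare-variant sharing in families.

Given the population fraction *f* of individuals carrying a qualifying rare
variant in a gene (from a :class:`~sorva.freqtable.BurdenTable`), these
functions compute the probability that the sharing pattern observed among
affected individuals — unrelated probands, sib pairs, consanguineous
relatives, larger pedigrees, or a mixture of unrelated cases and one kind of
familial unit — arose by chance.  Every test is an upper binomial tail on the
number of "successful" familial units, with the per-unit success probability
scaled by how much genome the unit's members share identical by descent:

========================  ====================================
unit                      per-unit chance probability
========================  ====================================
unrelated proband         f
sib pair, homozygous      f/4
consanguineous pair       f * (1/2)**(E-1)   (E = path edges)
relatives sharing het     r * f              (r = relationship
                          coefficient; (1/2)**(s-1) for s
                          members sharing by descent)
de novo in a proband      l_tx * d * c
========================  ====================================

For mixed designs (n unrelated singletons plus m familial units) the P-value
sums, over all outcomes at most as likely as the observed one, a mixture
probability built from the pooled per-unit failure rate and a binomial
allocation of successes between singletons and familial units.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction

import numpy as np
from scipy.stats import binom

from .freqtable import BurdenTable, Zygosity, query_fraction, zero_count_substitute

__all__ = [
    "DeNovoParams",
    "UnitKind",
    "ZygosityModel",
    "FamilialUnit",
    "StudyDesign",
    "SignificanceResult",
    "pvalue_denovo",
    "pvalue_recurrent",
    "pvalue_sibpairs_hom",
    "pvalue_consanguineous",
    "pvalue_shared_het",
    "pvalue_combined",
    "bonferroni_correct",
    "evaluate_study",
]

#: Fraction of de novo events that are splice-site or nonsense (LOF-only
#: consequence threshold) and fraction that are protein-altering at all.
DENOVO_CONSEQUENCE_FRACTION = {"lof": 0.0285, "nonsyn": 0.7064}

_TIE_RTOL = 1e-12  # outcomes with probability equal to the observed (to within
# this relative tolerance) are counted in the tail summation


def _upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    return float(binom.sf(k - 1, n, p))


def _check_kn(k: int, n: int) -> None:
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")


def _check_f(f: float, name: str = "f") -> None:
    if f == 0:
        raise ValueError(
            f"{name} = 0: a zero carrier fraction makes the test degenerate; "
            "apply zero_count_substitute (1/(2N)) to obtain a finite, "
            "conservative a-priori probability"
        )
    if not 0 < f <= 1:
        raise ValueError(f"{name} must be in (0, 1], got {f}")


@dataclass(frozen=True)
class DeNovoParams:
    """Per-generation de novo mutation model for one transcript.

    Parameters
    ----------
    l_tx
        Transcript length in nucleotide bases.
    d
        Mean rate of de novo SNVs per nucleotide per generation.  There is no
        packaged default: supply a value from the mutation-rate literature and
        record its source in ``d_citation``.
    c
        Fraction of de novo events meeting the consequence threshold
        (0.0285 for splice-site/nonsense only, 0.7064 for all
        protein-altering events).
    """

    l_tx: float
    d: float
    c: float = DENOVO_CONSEQUENCE_FRACTION["lof"]
    d_citation: str = ""

    def __post_init__(self) -> None:
        if self.l_tx <= 0 or self.d <= 0:
            raise ValueError("l_tx and d must be positive")
        if not 0 <= self.c <= 1:
            raise ValueError(f"c must be in [0, 1], got {self.c}")
        if self.per_proband_probability > 1:
            raise ValueError(
                f"l_tx*d*c = {self.per_proband_probability} exceeds 1; "
                "not a probability"
            )

    @property
    def per_proband_probability(self) -> float:
        return self.l_tx * self.d * self.c


def pvalue_denovo(s: int, n: int, params: DeNovoParams) -> float:
    """P-value of independent de novo events in the same gene in s of n probands.

    The chance probability per proband is ``l_tx * d * c``; the P-value is the
    upper tail P(X >= s) of a Binomial(n, l_tx*d*c).
    """
    _check_kn(s, n)
    return _upper_tail(s, n, params.per_proband_probability)


def pvalue_recurrent(k: int, n: int, f: float) -> float:
    """P-value of k of n unrelated affecteds carrying a qualifying variant.

    ``f`` is the population carrier fraction matching the study's zygosity
    filter (homozygous, heterozygous, compound-het/hom, or either).
    """
    _check_kn(k, n)
    _check_f(f)
    return _upper_tail(k, n, f)


def pvalue_sibpairs_hom(k: int, n_pairs: int, f_hom: float) -> float:
    """P-value of k of n sib pairs sharing a homozygous qualifying variant.

    A sib pair shares a homozygous variant identical by descent with
    probability f_hom / 4.
    """
    _check_kn(k, n_pairs)
    _check_f(f_hom, "f_hom")
    return _upper_tail(k, n_pairs, 0.25 * f_hom)


def pvalue_consanguineous(k: int, n_pairs: int, f_het: float, E: int) -> float:
    """P-value of homozygous sharing between consanguineous relatives.

    ``E`` is the number of independent edges in the pedigree paths connecting
    the two sequenced individuals through a single common ancestor; the
    per-pair sharing probability is f_het * (1/2)**(E-1).
    """
    _check_kn(k, n_pairs)
    _check_f(f_het, "f_het")
    if not (isinstance(E, (int, np.integer)) and E >= 1):
        raise ValueError(f"E must be an integer >= 1, got {E}")
    return _upper_tail(k, n_pairs, f_het * 0.5 ** (E - 1))


def pvalue_shared_het(k: int, n_units: int, r: float, f_both: float) -> float:
    """P-value of heterozygous sharing within k of n familial units.

    ``r`` is the coefficient of relationship — the expected fraction of the
    genome shared identical by descent among the unit's affected members
    ((1/2)**(s-1) for s members sharing through a common ancestor; 1 reduces
    to the unrelated-proband test).
    """
    _check_kn(k, n_units)
    _check_f(f_both, "f_both")
    if not 0 < r <= 1:
        raise ValueError(f"r must be in (0, 1], got {r}")
    return _upper_tail(k, n_units, r * f_both)


def _combined_pmf_grid(
    n: int, m: int, f_both: float, r0: float, r1: float
) -> np.ndarray:
    """Mixture probability P_{n,m,a,b} over the (n+1) x (m+1) outcome grid.

    F = 1 - n/(n+m)*r0*f - m/(n+m)*r1*f is the pooled per-unit failure
    probability; P_{n,m,a,b} = P(X = n+m-a-b) * P(Y = a) with
    X ~ Binomial(n+m, F) and Y ~ Binomial(a+b, r0*n/(r0*n + r1*m)).
    """
    total = n + m
    F = 1.0 - (n / total) * r0 * f_both - (m / total) * r1 * f_both
    p_alloc = r0 * n / (r0 * n + r1 * m) if (r0 * n + r1 * m) > 0 else 0.0
    a = np.arange(n + 1)[:, None]
    b = np.arange(m + 1)[None, :]
    s = a + b
    return binom.pmf(total - s, total, F) * binom.pmf(a, s, p_alloc)


def _independent_pmf_grid(
    n: int, m: int, f_both: float, r0: float, r1: float
) -> np.ndarray:
    """Exact joint pmf of two independent binomials over the outcome grid."""
    pa = binom.pmf(np.arange(n + 1), n, r0 * f_both)
    pb = binom.pmf(np.arange(m + 1), m, r1 * f_both)
    return pa[:, None] * pb[None, :]


def pvalue_combined(
    n: int,
    m: int,
    k: int,
    j: int,
    f_both: float,
    r0: float = 1.0,
    r1: float = 0.5,
    method: str = "mixture",
) -> float:
    """P-value for k of n singletons and j of m familial units carrying variants.

    The study pools n unrelated affecteds (relationship coefficient ``r0``,
    normally 1) with m familial units of one kind (``r1``: 1/2 for sib pairs
    sharing heterozygous variants, but any coefficient is accepted — e.g.
    1/128 for a third-cousin doubleton).  The probability of each outcome
    (a, b) on the grid 0 <= a <= n, 0 <= b <= m is evaluated and the P-value
    is the sum over all outcomes whose probability does not exceed that of
    the observed (k, j), the observed outcome included.

    ``method="mixture"`` (default) uses the pooled-failure-rate mixture
    probability; ``method="independent"`` uses the exact joint distribution
    of two independent binomials (the mixture probabilities need not sum to 1
    over the restricted grid, which the exact alternative avoids).
    """
    if n < 0 or m < 0 or n + m == 0:
        raise ValueError("need n, m >= 0 and not both zero")
    if not (0 <= k <= n and 0 <= j <= m):
        raise ValueError(f"need 0 <= k <= n and 0 <= j <= m, got {(k, j)}")
    _check_f(f_both, "f_both")
    if m == 0:
        return pvalue_recurrent(k, n, r0 * f_both) if k >= 1 else 1.0
    if n == 0:
        return pvalue_shared_het(j, m, r1, f_both) if j >= 1 else 1.0
    if method == "mixture":
        grid = _combined_pmf_grid(n, m, f_both, r0, r1)
    elif method == "independent":
        grid = _independent_pmf_grid(n, m, f_both, r0, r1)
    else:
        raise ValueError(f"unknown method {method!r}")
    p_obs = grid[k, j]
    tail = grid[grid <= p_obs * (1.0 + _TIE_RTOL)]
    return float(min(tail.sum(), 1.0))


def bonferroni_correct(p: float, genes_tested: int) -> float:
    """Bonferroni correction by the number of genes targeted: min(1, p * G)."""
    if genes_tested < 1:
        raise ValueError("genes_tested must be >= 1")
    return min(1.0, p * genes_tested)


# ---------------------------------------------------------------------------
# Study designs and the dispatcher


class UnitKind(str, Enum):
    SINGLETON = "SINGLETON"
    SIB_PAIR = "SIB_PAIR"
    CONSANGUINEOUS_PAIR = "CONSANGUINEOUS_PAIR"
    SHARED_HET_GROUP = "SHARED_HET_GROUP"


class ZygosityModel(str, Enum):
    """Which sharing model the familial units follow."""

    HET_SHARING = "HET_SHARING"
    HOM_SHARING = "HOM_SHARING"


@dataclass(frozen=True)
class FamilialUnit:
    """One affected sampling unit: a proband, a sib pair, a consanguineous
    pair, or a larger group of relatives sharing a variant by descent.

    ``success`` records whether the unit carries/shares a qualifying variant.
    The relationship coefficient r defaults to (1/2)**(s-1) for a group of s
    members sharing through common ancestors (1 for a singleton, 1/2 for a
    sib pair); ``E`` (path edge count) applies to consanguineous pairs only.
    """

    kind: UnitKind
    size: int = 1
    success: bool = False
    r: float | None = None
    E: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("unit size must be >= 1")
        if self.kind is UnitKind.SINGLETON and self.size != 1:
            raise ValueError("a singleton has size 1")
        if self.kind in (UnitKind.SIB_PAIR, UnitKind.CONSANGUINEOUS_PAIR) and self.size != 2:
            raise ValueError(f"{self.kind.value} has size 2")
        if self.kind is UnitKind.CONSANGUINEOUS_PAIR:
            if self.E is None or self.E < 2:
                raise ValueError("a consanguineous pair needs path edge count E >= 2")
        if self.r is not None and not 0 < self.r <= 1:
            raise ValueError(f"r must be in (0, 1], got {self.r}")

    @property
    def relationship(self) -> float:
        """Coefficient of relationship r for the unit."""
        if self.r is not None:
            return self.r
        return 0.5 ** (self.size - 1)


@dataclass
class StudyDesign:
    """A collection of familial units with observed success indicators."""

    units: list[FamilialUnit]
    zygosity_model: ZygosityModel = ZygosityModel.HET_SHARING

    @property
    def singletons(self) -> list[FamilialUnit]:
        return [u for u in self.units if u.kind is UnitKind.SINGLETON]

    @property
    def multis(self) -> list[FamilialUnit]:
        return [u for u in self.units if u.kind is not UnitKind.SINGLETON]

    @property
    def n(self) -> int:
        return len(self.singletons)

    @property
    def m(self) -> int:
        return len(self.multis)

    @property
    def k(self) -> int:
        return sum(u.success for u in self.singletons)

    @property
    def j(self) -> int:
        return sum(u.success for u in self.multis)

    @classmethod
    def from_counts(
        cls,
        singletons: tuple[int, int] = (0, 0),
        sib_pairs: tuple[int, int] = (0, 0),
        zygosity_model: ZygosityModel = ZygosityModel.HET_SHARING,
    ) -> "StudyDesign":
        """Build a design from (total, successes) counts per unit kind."""
        n, k = singletons
        m, j = sib_pairs
        if not (0 <= k <= n and 0 <= j <= m):
            raise ValueError("successes cannot exceed unit counts")
        units = [
            FamilialUnit(UnitKind.SINGLETON, success=i < k) for i in range(n)
        ] + [
            FamilialUnit(UnitKind.SIB_PAIR, size=2, success=i < j) for i in range(m)
        ]
        return cls(units, zygosity_model)


@dataclass(frozen=True)
class SignificanceResult:
    """Raw and Bonferroni-corrected P-value plus the inputs that produced them."""

    p_value: float
    corrected_p_value: float | None
    genes_tested: int | None
    a_priori: float
    method: str


def evaluate_study(
    design: StudyDesign,
    table: BurdenTable | None = None,
    feature_id: str | None = None,
    f: float | Fraction | None = None,
    zero_substitute: bool = False,
    genes_tested: int | None = None,
    method: str = "mixture",
) -> SignificanceResult:
    """Select and evaluate the significance formula matching a study design.

    The a-priori carrier fraction comes either from ``f`` directly (a float
    or an exact ``Fraction`` such as ``Fraction(5, 2504)``) or from a burden
    table query for ``feature_id``.  With ``zero_substitute`` a zero carrier
    count is replaced by 1/(2N) before testing.  Designs supported: all
    singletons; all units of one familial kind; or singletons mixed with one
    familial kind (evaluated with the combined-outcome summation).  Mixtures
    of several familial kinds have no closed formula here and raise.
    """
    if f is None:
        if table is None or feature_id is None:
            raise ValueError("supply either f or (table, feature_id)")
        count = table.count(feature_id)
        n_cohort = table.cohort_size
        if zero_substitute:
            f_val = zero_count_substitute(count, n_cohort)
        else:
            f_val = query_fraction(table, feature_id)
    else:
        f_val = float(f)
        if zero_substitute and f_val == 0.0:
            raise ValueError(
                "zero_substitute with an explicit f requires the table "
                "(the substitution needs the cohort size N)"
            )
    kinds = {u.kind for u in design.multis}
    if len(kinds) > 1:
        raise ValueError(
            "designs mixing several familial unit kinds are outside the "
            "formula catalogue; evaluate each kind separately"
        )
    n, m, k, j = design.n, design.m, design.k, design.j
    if m == 0:
        p = pvalue_recurrent(k, n, f_val) if k >= 1 else 1.0
        tag = "recurrent"
    elif n == 0:
        kind = kinds.pop()
        rs = {u.relationship for u in design.multis}
        if kind is UnitKind.CONSANGUINEOUS_PAIR:
            Es = {u.E for u in design.multis}
            if len(Es) > 1:
                raise ValueError("consanguineous units disagree on E")
            p = pvalue_consanguineous(j, m, f_val, Es.pop()) if j >= 1 else 1.0
            tag = "consanguineous"
        elif kind is UnitKind.SIB_PAIR and design.zygosity_model is ZygosityModel.HOM_SHARING:
            p = pvalue_sibpairs_hom(j, m, f_val) if j >= 1 else 1.0
            tag = "sib_pairs_hom"
        else:
            if len(rs) > 1:
                raise ValueError("familial units disagree on relationship coefficient")
            p = pvalue_shared_het(j, m, rs.pop(), f_val) if j >= 1 else 1.0
            tag = "shared_het"
        p = float(p)
    else:
        kind = kinds.pop()
        units = design.multis
        if kind is UnitKind.CONSANGUINEOUS_PAIR:
            Es = {u.E for u in units}
            if len(Es) > 1:
                raise ValueError("consanguineous units disagree on E")
            r1 = 0.5 ** (Es.pop() - 1)
        else:
            rs = {u.relationship for u in units}
            if len(rs) > 1:
                raise ValueError("familial units disagree on relationship coefficient")
            r1 = 0.25 if (
                kind is UnitKind.SIB_PAIR
                and design.zygosity_model is ZygosityModel.HOM_SHARING
            ) else rs.pop()
        p = pvalue_combined(n, m, k, j, f_val, r0=1.0, r1=r1, method=method)
        tag = f"combined[{method}]"
    corrected = bonferroni_correct(p, genes_tested) if genes_tested else None
    return SignificanceResult(
        p_value=float(p),
        corrected_p_value=corrected,
        genes_tested=genes_tested,
        a_priori=f_val,
        method=tag,
    )
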