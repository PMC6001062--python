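import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 300-individual synthetic cohort with autosomal and X genes."""
    from sorva.synthetic import CohortSpec, GeneSpec, SiteSpec, simulate_cohort

    spec = CohortSpec(
        n_individuals=300,
        genes=[
            GeneSpec(
                "GENE_A",
                [
                    SiteSpec(0.04, 0.002, "missense_variant"),
                    SiteSpec(0.02, 0.0, "stop_gained"),
                    SiteSpec(0.01, 0.001, "frameshift_variant"),
                ],
                chrom="1",
                start=1_000,
            ),
            GeneSpec(
                "GENE_B",
                [SiteSpec(0.03, 0.0, "missense_variant"), SiteSpec(0.005, 0.0, "splice_donor_variant")],
                chrom="2",
                start=50_000,
            ),
            GeneSpec(
                "GENE_X",
                [SiteSpec(0.05, 0.01, "missense_variant")],
                chrom="X",
                start=9_000,
            ),
        ],
        male_fraction=0.5,
        populations={"EUR": 0.6, "AFR": 0.4},
        seed=7,
    )
    paths = simulate_cohort(spec, tmp_path_factory.mktemp("cohort"))
    return spec, paths


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    from sorva.collapse import read_cohort

    _, paths = small_cohort
    matrix = read_cohort(paths.vcf, paths.annotations, paths.samples)
    matrix.compute_mafs()
    return matrix
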