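import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """One generated synthetic world shared by read-only tests."""
    from odontoprio.synthetic_data import generate_world

    return generate_world(seed=11)


@pytest.fixture()
def world_dir(tmp_path, small_world):
    from odontoprio.synthetic_data import write_world

    write_world(small_world, tmp_path / "world")
    return tmp_path / "world"


def make_world_config(d, seed):
    """Pipeline config pointing at a serialized world directory."""
    from odontoprio.pipeline import PipelineConfig

    return PipelineConfig(
        segmentation_target=str(d / "segmentation_tooth.bed"),
        segmentation_backgrounds=[
            str(d / f"segmentation_background_{i}.bed") for i in (1, 2, 3)
        ],
        genes=str(d / "genes.tsv"),
        chrom_sizes=str(d / "chrom_sizes.tsv"),
        variants=str(d / "variants.tsv"),
        vista=str(d / "vista.bed"),
        markers=str(d / "markers.tsv"),
        de=str(d / "de.tsv"),
        modules=str(d / "modules.tsv"),
        ontology_genes=str(d / "ontology_genes.txt"),
        gwas_traits=["odontogenesis", "tooth eruption"],
        seed=seed,
    )
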