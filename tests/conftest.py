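import numpy as np
import pytest

from tagpower.panel_io import HaplotypePanel, build_panel
from tagpower.synthetic_data import SimulationConfig, generate_panel


def make_panel(columns, positions=None, chrom="1", ids=None) -> HaplotypePanel:
    """Panel from a list of 0/1 haplotype columns (each of even length)."""
    matrix = np.array(columns, dtype=np.uint8).T
    n_var = matrix.shape[1]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_var)]
    if ids is None:
        ids = [f"v{j + 1}" for j in range(n_var)]
    alleles = [("A", "G")] * n_var
    sample_ids = [f"s{k}" for k in range(matrix.shape[0] // 2)]
    return build_panel(ids, [chrom] * n_var, positions, alleles, matrix, sample_ids)


@pytest.fixture(scope="session")
def mosaic_panel() -> HaplotypePanel:
    """One seeded block-LD panel shared by the qualitative checks."""
    return generate_panel(
        SimulationConfig(
            seed=3, n_samples=200, n_variants=800, region_length=400_000
        )
    )


@pytest.fixture
def toy_vcf(tmp_path):
    def _write(body: str, samples=("NA1", "NA2")):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
            + body
        )
        path = tmp_path / "toy.vcf"
        path.write_text(text)
        return path

    return _write
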