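import warnings

import numpy as np
import pandas as pd
import pytest

from nascenttx import synthetic
from nascenttx.genomic_io import BinnedCoverage, GeneAnnotation, GenomeLayout
from nascenttx.pipeline import PipelineConfig, run


@pytest.fixture(scope="session")
def small_genome():
    """2-Mbp toy genome with 20 genes and 30 enhancer-state sites."""
    return synthetic.generate_genome(1, 2_000_000, 20, 30, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return synthetic.generate_programs(small_genome, n_cell_lines=4,
                                       frac_specific=0.3, seed=1,
                                       n_replicates=2)


@pytest.fixture(scope="session")
def clean_coverage(small_genome, small_truth):
    return synthetic.simulate_coverage(small_genome, small_truth, seed=2,
                                       noise="none")


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on a small genome, shared across tests."""
    cfg = PipelineConfig(chrom_length_bp=1_000_000, n_genes=12,
                         n_enhancer_states=18, n_cell_lines=4,
                         n_snp_null_sets=100, n_ep_null_sets=20)
    outdir = tmp_path_factory.mktemp("pipeline_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run(cfg, str(outdir))
    return cfg, outdir, bundle


def toy_layout(n_bins=50, bin_width=200, chrom="chr1"):
    return GenomeLayout(((chrom, n_bins * bin_width),), bin_width=bin_width)


def coverage_from_arrays(plus, minus, bin_width=200, chrom="chr1",
                         sample="s1"):
    plus = np.asarray(plus, dtype=np.int64)
    minus = np.asarray(minus, dtype=np.int64)
    return {
        "+": BinnedCoverage(sample, "+", bin_width, {chrom: plus}),
        "-": BinnedCoverage(sample, "-", bin_width, {chrom: minus}),
    }


def single_gene_annotation(chrom="chr1", start=8_000, end=20_000, strand="+",
                           gene_id="G0001", biotype="protein_coding"):
    genes = pd.DataFrame([{
        "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand, "biotype": biotype,
    }])
    exons = pd.DataFrame([
        {"gene_id": gene_id, "chrom": chrom, "start": start,
         "end": start + (end - start) // 2, "strand": strand},
        {"gene_id": gene_id, "chrom": chrom, "start": start + (end - start) // 2,
         "end": end, "strand": strand},
    ])
    return GeneAnnotation(genes, exons)
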