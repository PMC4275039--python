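import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import trnsel
from trnsel import variant_annotation as va

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One emitted genome fixture (FASTA/GFF3/variants) with its truth."""
    outdir = tmp_path_factory.mktemp("fixture")
    truth = trnsel.simulate_fixture_truth(n_genes=8, seed=7)
    paths = trnsel.emit_fixture_genome(truth, outdir, seed=7)
    return truth, paths


@pytest.fixture(scope="session")
def tiny_tabulated(fixture_bundle):
    truth, paths = fixture_bundle
    genes = va.read_gff3(paths["gff3"])
    genomes = va.read_fasta(paths["fasta"])
    chrom_lengths = {c: len(s) for c, s in genomes.items()}
    variants = va.read_variant_table(paths["variants"])
    regions = va.extract_upstream_regions(genes, chrom_lengths)
    counts = va.tabulate_mk_counts(genes, regions, variants, genomes)
    return truth, genes, genomes, regions, variants, counts


def truth_metrics_frame(truth) -> pd.DataFrame:
    """Minimal NodeMetrics-like frame from generator truth (no centralities)."""
    genes = truth.genes
    df = pd.DataFrame({
        "node_id": genes["gene_id"],
        "role": genes["role"],
        "k": genes["degree"],
        "betweenness": 0.0,
        "eigenvector": 0.0,
        "hub_tf": (genes["role"] == "TF") & genes["hub"],
        "hub_target": (genes["role"] == "target") & genes["hub"],
    })
    return df


def roundtrip_counts(seed: int, n_genes: int = 8, mean_count: float = 1.5,
                     tmpdir=None):
    """Emit a fixture and re-tabulate it; returns (ledger, tabulated)."""
    import tempfile
    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        truth = trnsel.simulate_fixture_truth(n_genes, seed, mean_count)
        paths = trnsel.emit_fixture_genome(truth, d, seed)
        genes = va.read_gff3(paths["gff3"])
        genomes = va.read_fasta(paths["fasta"])
        chrom_lengths = {c: len(s) for c, s in genomes.items()}
        variants = va.read_variant_table(paths["variants"])
        regions = va.extract_upstream_regions(genes, chrom_lengths)
        counts = va.tabulate_mk_counts(genes, regions, variants, genomes)
    led = truth.ledger_counts().set_index("gene_id")
    tab = counts.set_index("gene_id")[["PS", "PR", "FS", "FR", "PC", "FC"]]
    led = led.reindex(tab.index, fill_value=0)
    return led, tab
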