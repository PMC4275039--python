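"""Upstream-region extraction, codon classification and MK tabulation."""

import numpy as np
import pandas as pd
import pytest

from trnsel import variant_annotation as va


def gene(gene_id="g1", chrom="chr1", strand="+", cds=((5000, 5300),),
         **kw):
    return va.GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                        cds_intervals=list(cds), **kw)


CHROM_LEN = {"chr1": 20_000}


class TestGeneModel:
    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            gene(cds=((0, 10),))

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            gene(cds=((0, 30), (20, 50)))


class TestUpstreamRegions:
    def test_full_window_plus_strand(self):
        regions = va.extract_upstream_regions([gene()], CHROM_LEN)
        assert (regions[0].start, regions[0].end) == (4000, 5000)
        assert regions[0].length == 1000

    def test_opposite_strand_truncation(self):
        # blocker body covers [4400, 4700): keep only [4700, 5000)
        blocker = gene("g2", strand="-", cds=((4400, 4700),))
        regions = va.extract_upstream_regions([gene(), blocker], CHROM_LEN)
        r = {r.gene_id: r for r in regions}
        assert (r["g1"].start, r["g1"].end) == (4700, 5000)
        assert r["g1"].length == 300

    def test_whole_region_exclusion_flag(self):
        blocker = gene("g2", strand="-", cds=((4400, 4700),))
        regions = va.extract_upstream_regions([gene(), blocker], CHROM_LEN,
                                              truncate=False)
        assert "g1" not in {r.gene_id for r in regions}

    def test_chromosome_start_omits_gene(self):
        g = gene(cds=((0, 300),))
        assert va.extract_upstream_regions([g], CHROM_LEN) == []

    def test_minus_strand_window_and_clip(self):
        g = gene(strand="-", cds=((19_500, 19_800),))
        r = va.extract_upstream_regions([g], CHROM_LEN)[0]
        assert (r.start, r.end) == (19_800, 20_000)

    def test_same_strand_overlap_flagged_not_truncated(self):
        neighbour = gene("g2", strand="+", cds=((4200, 4500),))
        regions = va.extract_upstream_regions([gene(), neighbour], CHROM_LEN)
        r = {r.gene_id: r for r in regions}
        assert r["g1"].length == 1000
        assert r["g1"].same_strand_overlap

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            va.extract_upstream_regions([gene(chrom="chrX")], CHROM_LEN)


def _genome_with(codon_seq, start=5000, chrom_len=20_000, seed=0):
    rng = np.random.default_rng(seed)
    genome = "".join(rng.choice(list("ACGT"), size=chrom_len))
    return genome[:start] + codon_seq + genome[start + len(codon_seq):]


class TestClassifyCodingVariant:
    @pytest.mark.parametrize("codon,off,alt,expected", [
        ("GGA", 2, "C", "synonymous"),      # Gly -> Gly
        ("AAA", 0, "G", "nonsynonymous"),   # Lys -> Glu
        ("TAC", 2, "A", "nonsense"),        # Tyr -> stop
    ])
    def test_plus_strand_codon_changes(self, codon, off, alt, expected):
        seq = "ATG" + codon + "TAA"
        genome = _genome_with(seq)
        g = gene(cds=((5000, 5009),))
        site = va.VariantSite("chr1", 5003 + off, seq[3 + off], alt,
                              "polymorphic")
        assert va.classify_coding_variant(g, genome, site) == expected

    def test_minus_strand_synonymous(self):
        # sense GGA -> GGC on the minus strand: genomic revcomp is TCC -> GCC
        sense = "ATG" + "GGA" + "TAA"
        rc = sense[::-1].translate(str.maketrans("ACGT", "TGCA"))
        genome = _genome_with(rc)
        g = gene(strand="-", cds=((5000, 5009),))
        # sense position 5 (A of GGA) sits at genomic 5000 + (9-1-5) = 5003
        site = va.VariantSite("chr1", 5003, "T", "G", "polymorphic")
        assert va.classify_coding_variant(g, genome, site) == "synonymous"

    def test_outside_cds_is_non_coding(self):
        genome = _genome_with("ATGGGATAA")
        g = gene(cds=((5000, 5009),))
        site = va.VariantSite("chr1", 4000, genome[4000],
                              "A" if genome[4000] != "A" else "C",
                              "polymorphic")
        assert va.classify_coding_variant(g, genome, site) == "non_coding"

    def test_reference_mismatch_raises(self):
        genome = _genome_with("ATGGGATAA")
        g = gene(cds=((5000, 5009),))
        wrong = "C" if genome[5004] != "C" else "G"
        site = va.VariantSite("chr1", 5004, wrong, "T", "polymorphic")
        with pytest.raises(va.DataIntegrityError):
            va.classify_coding_variant(g, genome, site)


class TestSiteOpportunities:
    @pytest.mark.parametrize("codon,l_syn", [
        ("TTT", 1.0 / 3.0),   # only TTT->TTC is silent among 9 mutations
        ("GGG", 1.0),         # third position fully degenerate
    ])
    def test_single_codon_opportunities(self, codon, l_syn):
        genome = _genome_with(codon)
        g = gene(cds=((5000, 5003),))
        L_syn, L_repl = va.compute_site_opportunities(g, genome)
        assert L_syn == pytest.approx(l_syn)
        assert L_repl == pytest.approx(3.0 - l_syn)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_cds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        seq = "".join(rng.choice(list("ACGT"), size=3 * n))
        genome = _genome_with(seq)
        strand = "+" if seed % 2 else "-"
        g = gene(strand=strand, cds=((5000, 5000 + 3 * n),))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # random CDS may hold stops
            L_syn, L_repl = va.compute_site_opportunities(g, genome)
        assert L_syn + L_repl == pytest.approx(3 * n)

    def test_internal_stop_warns(self):
        genome = _genome_with("ATGTAAGGG")
        g = gene(cds=((5000, 5009),))
        with pytest.warns(UserWarning, match="internal stop"):
            va.compute_site_opportunities(g, genome)


class TestTabulate:
    def _setup(self):
        seq = "ATG" + "GGA" + "AAA" + "TAA"
        genome = _genome_with(seq)
        g = gene(cds=((5000, 5012),))
        regions = va.extract_upstream_regions([g], CHROM_LEN)
        return genome, g, regions

    def test_three_variant_example(self):
        genome, g, regions = self._setup()
        variants = [
            va.VariantSite("chr1", 5005, "A", "C", "polymorphic"),  # GGA->GGC
            va.VariantSite("chr1", 5006, "A", "G", "fixed"),        # AAA->GAA
            va.VariantSite("chr1", 4500, genome[4500],
                           "A" if genome[4500] != "A" else "T", "fixed"),
        ]
        counts = va.tabulate_mk_counts([g], regions, variants,
                                       {"chr1": genome})
        row = counts.iloc[0]
        assert (row.PS, row.FR, row.FC) == (1, 1, 1)
        assert row[["PR", "FS", "PC"]].sum() == 0

    def test_nonsense_excluded_but_reported(self):
        genome, g, regions = self._setup()
        variants = [va.VariantSite("chr1", 5009, "T", "C", "fixed")]  # TAA->CAA stop-loss
        counts = va.tabulate_mk_counts([g], regions, variants,
                                       {"chr1": genome})
        assert counts.iloc[0][["PS", "PR", "FS", "FR"]].sum() == 0
        assert counts.attrs["exclusions"][0]["reason"] == "nonsense"

    def test_truncated_away_variant_counts_nowhere(self):
        genome, g, regions = self._setup()
        blocker = gene("g2", strand="-", cds=((4400, 4700),))
        genes = [g, blocker]
        regions = va.extract_upstream_regions(genes, CHROM_LEN)
        # 4200 is in the truncated-away part of g1's window and in no CDS
        pos = 4200
        assert not any(bg.contains(pos) for bg in genes)
        v = va.VariantSite("chr1", pos, genome[pos],
                           "A" if genome[pos] != "A" else "T", "fixed")
        counts = va.tabulate_mk_counts(genes, regions, [v],
                                       {"chr1": genome})
        # the blocker's own coding cells are untouched and g1 gets nothing
        assert counts[["PS", "PR", "FS", "FR", "PC", "FC"]].to_numpy().sum() == 0

    def test_conflicting_status_raises(self):
        genome, g, regions = self._setup()
        variants = [
            va.VariantSite("chr1", 5005, "A", "C", "polymorphic"),
            va.VariantSite("chr1", 5005, "A", "G", "fixed"),
        ]
        with pytest.raises(va.DataIntegrityError, match="both polymorphic"):
            va.tabulate_mk_counts([g], regions, variants, {"chr1": genome})

    def test_opposite_strand_cds_overlap_ambiguous(self):
        seq = "ATG" + "GGA" + "AAA" + "TAA"
        genome = _genome_with(seq)
        g1 = gene(cds=((5000, 5012),))
        g2 = gene("g2", strand="-", cds=((4998, 5016),))
        regions = []
        v = va.VariantSite("chr1", 5005, "A", "C", "polymorphic")
        counts = va.tabulate_mk_counts([g1, g2], regions, [v],
                                       {"chr1": genome})
        assert counts[["PS", "PR", "FS", "FR"]].to_numpy().sum() == 0
        assert counts.attrs["exclusions"][0]["reason"] == "ambiguous_coding"

    def test_every_variant_in_at_most_one_cell(self, tiny_tabulated):
        truth, genes, genomes, regions, variants, counts = tiny_tabulated
        total = counts[["PS", "PR", "FS", "FR", "PC", "FC"]].to_numpy().sum()
        assert total <= len(variants)

    def test_average_region_length_below_window(self, tiny_tabulated):
        _, genes, genomes, regions, _, _ = tiny_tabulated
        mean_len = np.mean([r.length for r in regions])
        assert mean_len < 1000


def _mirror_fixture(genes, genomes, variants):
    """Reverse-complement the whole fixture (coordinates, strands, alleles)."""
    comp = str.maketrans("ACGT", "TGCA")
    mirrored_genomes = {c: s.translate(comp)[::-1] for c, s in genomes.items()}
    lengths = {c: len(s) for c, s in genomes.items()}
    m_genes = []
    for g in genes:
        L = lengths[g.chrom]
        iv = [(L - e, L - s) for s, e in g.cds_intervals]
        m_genes.append(va.GeneModel(
            gene_id=g.gene_id, chrom=g.chrom,
            strand="-" if g.strand == "+" else "+",
            cds_intervals=sorted(iv)))
    m_vars = [va.VariantSite(v.chrom, lengths[v.chrom] - 1 - v.pos,
                             v.ref.translate(comp), v.alt.translate(comp),
                             v.status)
              for v in variants]
    return m_genes, mirrored_genomes, m_vars


def test_reverse_complement_symmetry(tiny_tabulated):
    truth, genes, genomes, regions, variants, counts = tiny_tabulated
    m_genes, m_genomes, m_vars = _mirror_fixture(genes, genomes, variants)
    m_regions = va.extract_upstream_regions(
        m_genes, {c: len(s) for c, s in m_genomes.items()})
    m_counts = va.tabulate_mk_counts(m_genes, m_regions, m_vars, m_genomes)
    cols = ["PS", "PR", "FS", "FR", "PC", "FC", "L_syn", "L_repl", "L_reg"]
    a = counts.set_index("gene_id")[cols].sort_index()
    b = m_counts.set_index("gene_id")[cols].sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_gff3_fasta_variant_io_roundtrip(tmp_path, tiny_tabulated):
    _, genes, genomes, _, variants, _ = tiny_tabulated
    va.write_gff3(genes, tmp_path / "x.gff3")
    va.write_fasta(genomes, tmp_path / "x.fa")
    back_genes = va.read_gff3(tmp_path / "x.gff3")
    assert {g.gene_id for g in back_genes} == {g.gene_id for g in genes}
    by_id = {g.gene_id: g for g in back_genes}
    for g in genes:
        assert by_id[g.gene_id].cds_intervals == g.cds_intervals
        assert by_id[g.gene_id].strand == g.strand
    assert va.read_fasta(tmp_path / "x.fa") == genomes
    led = pd.DataFrame([v.__dict__ for v in variants])
    va.write_variant_table(led, tmp_path / "v.tsv")
    back = va.read_variant_table(tmp_path / "v.tsv")
    assert back == variants


def test_vcf_adapter(tmp_path, tiny_tabulated):
    _, genes, genomes, _, variants, _ = tiny_tabulated
    chrom = genes[0].chrom
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=STATUS,Number=1,Type=String,Description="x">',
             f"##contig=<ID={chrom},length={len(genomes[chrom])}>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in variants[:10]:
        lines.append(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                     f"STATUS={v.status}")
    path = tmp_path / "v.vcf"
    path.write_text("\n".join(lines) + "\n")
    back = va.read_variants_vcf(path)
    assert back == variants[:10]
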