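"""Gene models, upstream cis-regulatory regions and MK count tabulation.

Coordinates are 0-based half-open everywhere inside the package; GFF3 and
variant-table I/O convert from/to the 1-based inclusive file conventions.

The putative cis-regulatory region of a gene is the window (default 1000 bp)
immediately 5' of its start codon on its own strand.  Portions overlapping
gene bodies on the complementary strand are truncated away (whole-region
exclusion is available via ``truncate=False``); same-strand upstream
overlaps are not truncated but flagged.  Genes whose region truncates to
length zero are omitted.

MK counting assigns every variant to at most one (gene, class) cell:
variants inside exactly one gene's CDS are classified by strand-aware codon
translation under the standard genetic code (nonsense changes are reported
but excluded from the counts); variants inside upstream regions count as
regulatory, resolved to the gene with the strictly nearest start codon when
regions overlap; everything ambiguous is excluded and logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class DataIntegrityError(ValueError):
    """Input data contradicts itself (e.g. variant ref != genome base)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    is_tf: bool | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        iv = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        for (s, e) in iv:
            if e <= s:
                raise ValueError(f"empty CDS interval {s, e} in {self.gene_id}")
        for (_, e1), (s2, _) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3")
        self.cds_intervals = iv

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent of the gene body."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the 5'-most base of the start codon."""
        if self.strand == "+":
            return self.cds_intervals[0][0]
        return self.cds_intervals[-1][1] - 1

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals)


@dataclass(frozen=True)
class RegulatoryRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    same_strand_overlap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int          # 0-based
    ref: str
    alt: str
    status: str       # polymorphic | fixed

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.status not in ("polymorphic", "fixed"):
            raise ValueError(f"unknown status {self.status!r}")


def sense_coordinates(gene: GeneModel) -> np.ndarray:
    """Genomic positions of the CDS in 5'->3' sense order."""
    pieces = [np.arange(s, e) for s, e in gene.cds_intervals]
    coords = np.concatenate(pieces)
    if gene.strand == "-":
        coords = coords[::-1]
    return coords


# ---------------------------------------------------------------------------
# upstream regions
# ---------------------------------------------------------------------------

def extract_upstream_regions(genes: list[GeneModel],
                             chrom_lengths: dict[str, int],
                             window: int = 1000,
                             truncate: bool = True) -> list[RegulatoryRegion]:
    """Putative cis-regulatory window upstream of each gene's start codon.

    With ``truncate=True`` (default) the portion overlapping any
    complementary-strand gene body is removed, keeping the part adjacent to
    the start codon; with ``truncate=False`` any such overlap discards the
    whole region.  Regions are clipped at chromosome ends; empty regions
    drop their gene from the result.
    """
    regions: list[RegulatoryRegion] = []
    for gene in genes:
        if gene.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {gene.chrom!r} for "
                             f"{gene.gene_id}")
        clen = chrom_lengths[gene.chrom]
        others = [g for g in genes
                  if g.chrom == gene.chrom and g.gene_id != gene.gene_id]
        if gene.strand == "+":
            hi = gene.span[0]
            lo = max(0, hi - window)
        else:
            lo = gene.span[1]
            hi = min(clen, lo + window)
        same_overlap = False
        for other in others:
            os_, oe = other.span
            if oe <= lo or os_ >= hi:
                continue
            if other.strand == gene.strand:
                same_overlap = True
                continue
            if not truncate:
                lo, hi = 0, 0
                break
            if gene.strand == "+":
                lo = max(lo, min(oe, hi))
            else:
                hi = min(hi, max(os_, lo))
        if hi - lo <= 0:
            logger.info("gene %s: upstream region empty after truncation; "
                        "omitted", gene.gene_id)
            continue
        regions.append(RegulatoryRegion(gene.gene_id, gene.chrom, lo, hi,
                                        same_strand_overlap=same_overlap))
    return regions


# ---------------------------------------------------------------------------
# codon classification and site opportunities
# ---------------------------------------------------------------------------

_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _TABLE[stop] = "*"
    return _TABLE


def classify_coding_variant(gene: GeneModel, genome: str,
                            site: VariantSite) -> str:
    """synonymous / nonsynonymous / nonsense / non_coding for one variant."""
    if site.chrom != gene.chrom:
        raise ValueError("variant and gene are on different chromosomes")
    if genome[site.pos].upper() != site.ref.upper():
        raise DataIntegrityError(
            f"variant ref {site.ref} at {site.chrom}:{site.pos} disagrees "
            f"with genome base {genome[site.pos]}")
    coords = sense_coordinates(gene)
    hit = np.nonzero(coords == site.pos)[0]
    if hit.size == 0:
        return "non_coding"
    j = int(hit[0])
    ci = j // 3
    codon_pos = coords[3 * ci:3 * ci + 3]
    bases = [genome[p].upper() for p in codon_pos]
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    ref_codon = "".join(bases)
    alt_base = site.alt.upper()
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    off = j - 3 * ci
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1:]
    table = _codon_table()
    aa_ref, aa_alt = table[ref_codon], table[alt_codon]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*" or aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def compute_site_opportunities(gene: GeneModel, genome: str
                               ) -> tuple[float, float]:
    """Nei-Gojobori-style synonymous/replacement site counts.

    Each codon contributes, for its 9 possible point mutations, the fraction
    that are silent to L_syn and the remainder to L_repl, so
    L_syn + L_repl equals the CDS length exactly.
    """
    table = _codon_table()
    coords = sense_coordinates(gene)
    seq = [genome[p].upper() for p in coords]
    if gene.strand == "-":
        seq = [b.translate(_COMPLEMENT) for b in seq]
    sense = "".join(seq)
    n_cod = len(sense) // 3
    L_syn = 0.0
    for ci in range(n_cod):
        codon = sense[3 * ci:3 * ci + 3]
        aa = table.get(codon)
        if aa is None:
            raise DataIntegrityError(f"non-nucleotide codon {codon!r} in "
                                     f"{gene.gene_id}")
        if aa == "*" and ci < n_cod - 1:
            warnings.warn(f"internal stop codon in {gene.gene_id} "
                          f"(codon {ci})", stacklevel=2)
        n_syn = 0
        for off in range(3):
            for b in "ACGT":
                if b == codon[off]:
                    continue
                alt = codon[:off] + b + codon[off + 1:]
                if table[alt] == aa:
                    n_syn += 1
        L_syn += n_syn / 3.0
    return L_syn, gene.cds_length - L_syn


# ---------------------------------------------------------------------------
# variant assignment and tabulation
# ---------------------------------------------------------------------------

def assign_variant(genes: list[GeneModel], genomes: dict[str, str],
                   regions: list[RegulatoryRegion],
                   site: VariantSite) -> tuple[str, str | None]:
    """Resolve one variant to (class, gene_id) under the counting rules.

    Classes: synonymous, nonsynonymous, nonsense, regulatory, intergenic,
    ambiguous_coding, ambiguous_regulatory.  Coding containment takes
    precedence over regulatory containment.
    """
    cds_hits = [g for g in genes
                if g.chrom == site.chrom and g.contains(site.pos)]
    if len(cds_hits) >= 2:
        return "ambiguous_coding", None
    if len(cds_hits) == 1:
        gene = cds_hits[0]
        cls = classify_coding_variant(gene, genomes[site.chrom], site)
        return cls, gene.gene_id
    hits = [r for r in regions
            if r.chrom == site.chrom and r.contains(site.pos)]
    if not hits:
        return "intergenic", None
    if len(hits) == 1:
        return "regulatory", hits[0].gene_id
    # overlapping upstream windows: strictly nearest start codon wins
    gene_by_id = {g.gene_id: g for g in genes}
    dists = [(abs(site.pos - gene_by_id[r.gene_id].start_codon_pos), r)
             for r in hits]
    dists.sort(key=lambda t: t[0])
    if dists[0][0] == dists[1][0]:
        return "ambiguous_regulatory", None
    return "regulatory", dists[0][1].gene_id


_CLASS_TO_CELL = {
    ("synonymous", "polymorphic"): "PS",
    ("synonymous", "fixed"): "FS",
    ("nonsynonymous", "polymorphic"): "PR",
    ("nonsynonymous", "fixed"): "FR",
    ("regulatory", "polymorphic"): "PC",
    ("regulatory", "fixed"): "FC",
}

COUNT_COLUMNS = ["gene_id", "PS", "PR", "FS", "FR", "PC", "FC",
                 "L_syn", "L_repl", "L_reg"]


def tabulate_mk_counts(genes: list[GeneModel],
                       regions: list[RegulatoryRegion],
                       variants: list[VariantSite],
                       genomes: dict[str, str]) -> pd.DataFrame:
    """Per-gene MK count table for coding and regulatory contexts.

    Exclusions (ambiguous assignments, nonsense changes, reference
    mismatches) are logged and attached to the result as
    ``df.attrs["exclusions"]``.
    """
    seen: dict[tuple[str, int], str] = {}
    for v in variants:
        key = (v.chrom, v.pos)
        if key in seen and seen[key] != v.status:
            raise DataIntegrityError(
                f"position {v.chrom}:{v.pos} carries both polymorphic and "
                "fixed status")
        seen[key] = v.status

    counts = {g.gene_id: dict.fromkeys(
        ("PS", "PR", "FS", "FR", "PC", "FC"), 0) for g in genes}
    exclusions: list[dict] = []
    for v in variants:
        try:
            cls, gid = assign_variant(genes, genomes, regions, v)
        except DataIntegrityError as err:
            logger.warning("skipping variant %s:%d: %s", v.chrom, v.pos, err)
            exclusions.append({"chrom": v.chrom, "pos": v.pos,
                               "reason": "ref_mismatch"})
            continue
        cell = _CLASS_TO_CELL.get((cls, v.status))
        if cell is None or gid is None:
            exclusions.append({"chrom": v.chrom, "pos": v.pos,
                               "reason": cls, "gene_id": gid})
            continue
        counts[gid][cell] += 1

    region_len = {r.gene_id: r.length for r in regions}
    rows = []
    for g in genes:
        L_syn, L_repl = compute_site_opportunities(g, genomes[g.chrom])
        row = {"gene_id": g.gene_id, **counts[g.gene_id],
               "L_syn": L_syn, "L_repl": L_repl,
               "L_reg": region_len.get(g.gene_id, 0)}
        rows.append(row)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.attrs["exclusions"] = exclusions
    if exclusions:
        logger.info("%d variants excluded from MK counts", len(exclusions))
    return df


# ---------------------------------------------------------------------------
# file I/O (FASTA / GFF3 / variant TSV / VCF / count TSV)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genomes: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    """1-based inclusive GFF3 with gene and CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            if g.is_tf is not None:
                attrs += f";is_tf={int(g.is_tf)}"
            fh.write(f"{g.chrom}\ttrnsel\tgene\t{s + 1}\t{e}\t.\t{g.strand}"
                     f"\t.\t{attrs}\n")
            for (cs, ce) in g.cds_intervals:
                fh.write(f"{g.chrom}\ttrnsel\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{g.strand}\t0\tParent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end)
               for c in db.children(feat, featuretype="CDS")]
        is_tf = feat.attributes.get("is_tf")
        genes.append(GeneModel(
            gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
            cds_intervals=cds,
            is_tf=bool(int(is_tf[0])) if is_tf else None))
    return genes


def write_variant_table(ledger: pd.DataFrame, path) -> None:
    """TSV with 1-based positions (chrom, pos, ref, alt, status)."""
    out = ledger[["chrom", "pos", "ref", "alt", "status"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[VariantSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [VariantSite(str(r.chrom), int(r.pos) - 1, str(r.ref),
                        str(r.alt), str(r.status))
            for r in df.itertuples()]


def read_variants_vcf(path, status_tag: str = "STATUS") -> list[VariantSite]:
    """VCF adapter: per-record fixed/polymorphic status from an INFO tag."""
    import pysam
    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("skipping non-biallelic record at %s:%d",
                               rec.chrom, rec.pos)
                continue
            status = rec.info.get(status_tag)
            if isinstance(status, tuple):
                status = status[0]
            if status not in ("polymorphic", "fixed"):
                logger.warning("skipping record without %s tag at %s:%d",
                               status_tag, rec.chrom, rec.pos)
                continue
            sites.append(VariantSite(rec.chrom, rec.pos - 1, rec.ref,
                                     rec.alts[0], status))
    return sites


def write_count_table(counts: pd.DataFrame, path,
                      version: str = "0.1.0") -> None:
    with open(path, "w") as fh:
        fh.write(f"# trnsel.variant_annotation v{version}\n")
        counts[COUNT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_count_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
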