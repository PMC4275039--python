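"""Synthetic genomes, variant sets, MK counts and scale-free networks.

Everything downstream of this module (annotation, the selection model, the
network statistics and the group comparisons) is exercised against data
generated here with known ground truth:

* per-gene population-scaled selection coefficients drawn from truncated
  normal mixtures (the "paper-regulatory" preset plants 93% near-neutral /
  6% negative / 1% positive regulatory genes with mixture mean ~ -0.4; the
  "paper-coding" preset is symmetric with mean ~ 0);
* Poisson polymorphism/divergence count tables whose expectations follow
  the same log-linear structure the estimation model assumes, with the
  fixation-ratio mapping g(gamma) on the selected-fixed cell;
* directed TF->target networks whose out-degree tail follows a discrete
  power law;
* small multi-gene genome fixtures (FASTA + GFF3 + variant TSV) in which
  every planted variant occupies a concrete site whose annotation class and
  status are recorded in a ledger, for exact round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .selection_model import fixation_ratio

# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaMixture:
    """Truncated-normal mixture over true selection coefficients."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if not (len(self.weights) == len(self.means) == len(self.sds)
                == len(self.bounds)):
            raise ValueError("mixture component lists must have equal length")
        for m, sd, (lo, hi) in zip(self.means, self.sds, self.bounds):
            if sd <= 0:
                raise ValueError("component sd must be positive")
            if not lo < hi:
                raise ValueError("truncation bounds must satisfy lo < hi")
            if not (lo <= m <= hi):
                raise ValueError(
                    f"component mean {m} outside its truncation bounds "
                    f"({lo}, {hi})")

    def component_means(self) -> np.ndarray:
        out = []
        for m, sd, (lo, hi) in zip(self.means, self.sds, self.bounds):
            a, b = (lo - m) / sd, (hi - m) / sd
            out.append(stats.truncnorm.mean(a, b, loc=m, scale=sd))
        return np.asarray(out)

    def mean(self) -> float:
        """Analytic mixture mean of the true gamma distribution."""
        return float(np.dot(self.weights, self.component_means()))


#: named gamma mixtures.  The "paper-regulatory" weights encode a 93/6/1
#: near-neutral/negative/positive split; component means (-0.2, -4, +2)
#: are chosen so the mixture mean is ~ -0.4, and the sds make the near-neutral
#: component sharply peaked.
GAMMA_PRESETS: dict[str, GammaMixture] = {
    "paper-regulatory": GammaMixture(
        weights=(0.93, 0.06, 0.01),
        means=(-0.2, -4.0, 2.0),
        sds=(0.2, 0.75, 0.5),
        bounds=((-1.0, 1.0), (-np.inf, -1.0), (1.0, np.inf)),
    ),
    "paper-coding": GammaMixture(
        weights=(0.92, 0.04, 0.04),
        means=(0.0, -2.0, 2.0),
        sds=(0.2, 0.75, 0.75),
        bounds=((-1.0, 1.0), (-np.inf, -1.0), (1.0, np.inf)),
    ),
}

#: named power-law tail parameters; "paper-trn-tail" is the fitted TRN
#: connectedness tail (x_min = 42, alpha = 3.00).
POWER_LAW_PRESETS: dict[str, dict] = {
    "paper-trn-tail": {"alpha": 3.0, "x_min": 42},
}


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions.

    ``theta`` is the expected density of segregating silent sites per site
    in the sampled population (a deep resequencing sample of a hyperdiverse
    population), ``delta`` the log divergence:polymorphism per-site ratio,
    ``rho`` the mean log constraint offset of the selected class, and
    L_syn/L_repl/L_reg the per-gene site opportunities.
    """

    seed: int = 0
    n_tf: int = 200
    n_target: int = 1500
    degree_alpha: float = 2.5
    degree_xmin: int = 1
    degree_kmax: int = 10 ** 6
    gamma_preset: str | GammaMixture = "paper-regulatory"
    theta: float = 0.08
    theta_sd: float = 0.3
    delta: float = 0.8
    rho: float = -0.1
    rho_sd: float = 0.3
    L_syn: float = 500.0
    L_repl: float = 1500.0
    L_reg: float = 905.0
    hub_fraction: float = 0.20
    hub_gamma_shift: float = 0.0

    def __post_init__(self):
        if self.degree_alpha <= 1:
            raise ValueError("degree_alpha must exceed 1")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        for name in ("L_syn", "L_repl", "L_reg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mixture(self) -> GammaMixture:
        if isinstance(self.gamma_preset, GammaMixture):
            return self.gamma_preset
        return GAMMA_PRESETS[self.gamma_preset]


@dataclass
class SyntheticTruth:
    """Ledger of every planted quantity for recovery tests."""

    seed: int
    genes: pd.DataFrame | None = None          # per-gene truth (gamma, role, hub, ...)
    edges: pd.DataFrame | None = None
    degree_sequence: np.ndarray | None = None
    counts: dict = field(default_factory=dict)  # label -> planted count table
    variant_ledger: pd.DataFrame | None = None

    def ledger_counts(self) -> pd.DataFrame:
        """Aggregate the variant ledger into an MK-style count table."""
        if self.variant_ledger is None:
            raise ValueError("no variant ledger present")
        led = self.variant_ledger
        tab = (led.groupby(["gene_id", "mk_class"]).size()
                  .unstack(fill_value=0))
        for col in ("PS", "FS", "PR", "FR", "PC", "FC"):
            if col not in tab.columns:
                tab[col] = 0
        return (tab[["PS", "PR", "FS", "FR", "PC", "FC"]]
                .rename_axis(columns=None).reset_index())


# ---------------------------------------------------------------------------
# scale-free degrees and networks
# ---------------------------------------------------------------------------

def sample_power_law_degrees(n: int, alpha: float, x_min: int,
                             k_max: int = 10 ** 6,
                             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` degrees from the discrete power law P(k) ~ k^-alpha.

    Support is the integer range [x_min, k_max]; the probability mass is
    normalised over that range.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 (the zeta normaliser diverges)")
    if n < 0:
        raise ValueError("n must be non-negative")
    if not (1 <= x_min <= k_max):
        raise ValueError("need 1 <= x_min <= k_max")
    if n == 0:
        return np.array([], dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    support = np.arange(x_min, k_max + 1, dtype=float)
    with np.errstate(over="ignore"):
        pmf = support ** (-alpha)
    pmf /= pmf.sum()
    # inverse-CDF sampling; searchsorted keeps memory flat for large support
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    return (x_min + idx).astype(int)


def simulate_trn(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Directed TF->target edge list with planted degree sequence and hubs.

    TF out-degrees come from the discrete power law (clipped at the number
    of available targets); each TF's targets are sampled without
    replacement, so edges are unique and there are no self-loops.
    """
    from .network_analysis import hub_flags  # local import avoids a cycle

    if config.n_tf < 1 or config.n_target < 1:
        raise ValueError("need at least one TF and one target")
    rng = np.random.default_rng(config.seed)
    tf_ids = np.array([f"TF{i:04d}" for i in range(config.n_tf)])
    tg_ids = np.array([f"TG{i:05d}" for i in range(config.n_target)])
    degrees = sample_power_law_degrees(
        config.n_tf, config.degree_alpha, config.degree_xmin,
        config.degree_kmax, rng)
    degrees = np.minimum(degrees, config.n_target)
    rows = []
    for tf, k in zip(tf_ids, degrees):
        targets = rng.choice(tg_ids, size=int(k), replace=False)
        rows.extend((tf, t) for t in targets)
    edges = pd.DataFrame(rows, columns=["tf_id", "target_id"])
    in_deg = edges["target_id"].value_counts().reindex(tg_ids, fill_value=0)
    tf_hub = hub_flags(degrees, config.hub_fraction)
    tg_hub = hub_flags(in_deg.to_numpy(), config.hub_fraction)
    genes = pd.DataFrame({
        "gene_id": np.concatenate([tf_ids, tg_ids]),
        "role": ["TF"] * config.n_tf + ["target"] * config.n_target,
        "degree": np.concatenate([degrees, in_deg.to_numpy()]),
        "hub": np.concatenate([tf_hub, tg_hub]),
    })
    truth = SyntheticTruth(seed=config.seed, genes=genes, edges=edges,
                           degree_sequence=degrees.copy())
    return edges, truth


# ---------------------------------------------------------------------------
# selection coefficients and MK counts
# ---------------------------------------------------------------------------

def draw_gamma_profile(n_genes: int, preset: str | GammaMixture,
                       seed: int | np.random.Generator = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene true gamma values and their mixture-component labels."""
    mix = GAMMA_PRESETS[preset] if isinstance(preset, str) else preset
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(len(mix.weights), size=n_genes, p=mix.weights)
    gamma = np.empty(n_genes)
    for j, (m, sd, (lo, hi)) in enumerate(zip(mix.means, mix.sds, mix.bounds)):
        members = comp == j
        k = int(members.sum())
        if k == 0:
            continue
        a, b = (lo - m) / sd, (hi - m) / sd
        gamma[members] = stats.truncnorm.rvs(a, b, loc=m, scale=sd, size=k,
                                             random_state=rng)
    return gamma, comp


def simulate_counts(true_gamma: np.ndarray, config: SimulationConfig,
                    context: str = "regulatory",
                    seed: int | np.random.Generator = 0,
                    gene_ids: np.ndarray | None = None,
                    return_params: bool = False):
    """Poisson MK count table conditional on per-gene true gamma.

    Per gene i (theta_i log-normal around config.theta, rho_i normal around
    config.rho):

        PS  ~ Poi(theta_i * L_syn)
        FS  ~ Poi(theta_i * L_syn * exp(delta))
        Psel~ Poi(theta_i * L_sel * exp(rho_i))
        Fsel~ Poi(theta_i * L_sel * exp(rho_i) * exp(delta) * g(gamma_i))

    where the selected pair is (PR, FR) with L_repl for the coding context
    and (PC, FC) with L_reg for the regulatory context.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = np.asarray(true_gamma, dtype=float)
    n = len(gamma)
    g = fixation_ratio(gamma)
    if np.any(~np.isfinite(g)):
        raise FloatingPointError("non-finite fixation ratio for some gamma")
    if context == "coding":
        pcol, fcol, L_sel = "PR", "FR", config.L_repl
    elif context == "regulatory":
        pcol, fcol, L_sel = "PC", "FC", config.L_reg
    else:
        raise ValueError(f"unknown context {context!r}")
    theta_i = config.theta * np.exp(
        rng.normal(0.0, config.theta_sd, size=n) - config.theta_sd ** 2 / 2.0)
    rho_i = rng.normal(config.rho, config.rho_sd, size=n)
    lam_ps = theta_i * config.L_syn
    lam_fs = lam_ps * np.exp(config.delta)
    lam_pr = theta_i * L_sel * np.exp(rho_i)
    lam_fr = lam_pr * np.exp(config.delta) * g
    if gene_ids is None:
        gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    counts = pd.DataFrame({
        "gene_id": gene_ids,
        "PS": rng.poisson(lam_ps),
        "PR": 0, "FS": rng.poisson(lam_fs), "FR": 0,
        "PC": 0, "FC": 0,
        "L_syn": config.L_syn, "L_repl": config.L_repl, "L_reg": config.L_reg,
    })
    counts[pcol] = rng.poisson(lam_pr)
    counts[fcol] = rng.poisson(lam_fr)
    counts = counts[["gene_id", "PS", "PR", "FS", "FR", "PC", "FC",
                     "L_syn", "L_repl", "L_reg"]]
    if return_params:
        params = pd.DataFrame({"gene_id": gene_ids, "theta_i": theta_i,
                               "rho_i": rho_i, "gamma": gamma})
        return counts, params
    return counts


# ---------------------------------------------------------------------------
# genome fixtures
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = {}


def _codon_table() -> dict:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def simulate_fixture_truth(n_genes: int = 8, seed: int = 0,
                           mean_count: float = 1.5) -> SyntheticTruth:
    """Plan a small fixture: per-gene MK count targets to be planted."""
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = [f"FG{i:03d}" for i in range(n_genes)]
    cols = ["PS", "PR", "FS", "FR", "PC", "FC"]
    counts = pd.DataFrame(rng.poisson(mean_count, size=(n_genes, len(cols))),
                          columns=cols)
    counts.insert(0, "gene_id", gene_ids)
    truth = SyntheticTruth(seed=seed)
    truth.counts["fixture"] = counts
    return truth


def _random_body_codons(rng, n, need_synonymous):
    """Sense codons for a CDS body; guarantees codons with synonymous moves."""
    table = _codon_table()
    codons = [c for c in table if table[c] != "*"]
    syn_capable = [c for c in codons if _mutations_of(c, synonymous=True)]
    body = list(rng.choice(codons, size=n))
    if need_synonymous > 0:
        # make sure at least `need_synonymous` codons allow a silent change
        idx = rng.choice(n, size=min(n, max(need_synonymous * 2, 4)),
                         replace=False)
        for i in idx:
            body[i] = str(rng.choice(syn_capable))
    return body


def _mutations_of(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """(offset, alt base) point mutations of a codon, silent or not.

    Non-silent candidates exclude stop gains so that planted replacement
    variants are never nonsense.
    """
    table = _codon_table()
    aa = table[codon]
    out = []
    for off in range(3):
        for b in "ACGT":
            if b == codon[off]:
                continue
            alt = codon[:off] + b + codon[off + 1:]
            aa2 = table[alt]
            if synonymous and aa2 == aa:
                out.append((off, b))
            elif not synonymous and aa2 != aa and aa2 != "*":
                out.append((off, b))
    return out


def emit_fixture_genome(truth: SyntheticTruth, outdir, seed: int = 0,
                        window: int = 1000, max_tries: int = 50):
    """Write genome FASTA + gene GFF3 + variant TSV realising planted counts.

    The emitted gene set includes both strands and at least one head-to-head
    opposite-strand pair whose upstream windows are truncated by the
    neighbouring gene body.  Every planted variant is verified against the
    annotation module's own assignment rule before being written; the final
    ledger on ``truth.variant_ledger`` therefore matches
    ``tabulate_mk_counts`` exactly.
    """
    from . import variant_annotation as va

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = truth.counts.get("fixture")
    if plan is None:
        raise ValueError("truth carries no fixture count plan; see "
                         "simulate_fixture_truth")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    n_genes = len(plan)

    fasta = outdir / "genome.fa"
    gff = outdir / "genes.gff3"
    var = outdir / "variants.tsv"
    if n_genes == 0:
        fasta.write_text(f">{chrom}\n{''.join(rng.choice(_BASES, 60))}\n")
        gff.write_text("##gff-version 3\n")
        var.write_text("chrom\tpos\tref\talt\tstatus\n")
        truth.variant_ledger = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "status", "mk_class",
                     "gene_id"])
        return {"fasta": fasta, "gff3": gff, "variants": var}

    for attempt in range(max_tries):
        try:
            result = _emit_once(truth, plan, rng, chrom, window,
                                fasta, gff, var)
            return result
        except _PlacementError:
            continue
    raise RuntimeError(f"could not place planted variants after {max_tries} "
                       "layouts; counts likely exceed fixture capacity")


class _PlacementError(RuntimeError):
    pass


def _emit_once(truth, plan, rng, chrom, window, fasta, gff, var):
    from . import variant_annotation as va

    n_genes = len(plan)
    # --- strand/gap layout: gene 1 '-' and gene 2 '+' head-to-head ---------
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_genes)]
    gaps = [int(1100 + rng.integers(0, 400)) for _ in range(n_genes)]
    if n_genes >= 3:
        strands[1], strands[2] = "-", "+"
        gaps[2] = 600  # shared, truncated upstream gap of the pair
    genes = []
    seqs = {}
    cursor = 0
    for i, row in plan.iterrows():
        gid = row["gene_id"]
        need_coding = int(row[["PS", "PR", "FS", "FR"]].sum())
        n_body = max(40, 2 * need_coding + 8)
        body = _random_body_codons(rng, n_body,
                                   int(row["PS"] + row["FS"]))
        sense = "ATG" + "".join(body) + "TAA"
        L = len(sense)
        start = cursor + gaps[i]
        # one multi-interval gene to exercise codon-spanning intervals
        if i == 0 and n_body >= 10:
            cut = 3 * (n_body // 2) + 1  # mid-codon split
            intron = 120
            iv = [(start, start + cut), (start + cut + intron, start + L + intron)]
        else:
            iv = [(start, start + L)]
        genes.append(va.GeneModel(gene_id=gid, chrom=chrom, strand=strands[i],
                                  cds_intervals=iv))
        seqs[gid] = sense
        cursor = iv[-1][1]
    chrom_len = cursor + window + 300

    genome = rng.choice(_BASES, size=chrom_len)
    for gene in genes:
        sense = seqs[gene.gene_id]
        coords = va.sense_coordinates(gene)
        if gene.strand == "+":
            for j, pos in enumerate(coords):
                genome[pos] = sense[j]
        else:
            for j, pos in enumerate(coords):
                genome[pos] = sense[j].translate(_COMPLEMENT)
    genome_str = "".join(genome)
    genomes = {chrom: genome_str}
    chrom_lengths = {chrom: chrom_len}

    regions = va.extract_upstream_regions(genes, chrom_lengths, window=window)
    region_by_gene = {r.gene_id: r for r in regions}

    ledger_rows = []
    used_sites = set()
    used_codons = set()

    def place_coding(gene, silent, status, count):
        sense = seqs[gene.gene_id]
        coords = va.sense_coordinates(gene)
        n_cod = len(sense) // 3
        candidates = list(range(1, n_cod - 1))  # skip start and stop codons
        rng.shuffle(candidates)
        placed = 0
        for ci in candidates:
            if placed == count:
                break
            if (gene.gene_id, ci) in used_codons:
                continue
            codon = sense[3 * ci:3 * ci + 3]
            muts = _mutations_of(codon, synonymous=silent)
            if not muts:
                continue
            off, alt_sense = muts[rng.integers(len(muts))]
            j = 3 * ci + off
            pos = int(coords[j])
            if pos in used_sites:
                continue
            if gene.strand == "+":
                ref_g, alt_g = sense[j], alt_sense
            else:
                ref_g = sense[j].translate(_COMPLEMENT)
                alt_g = alt_sense.translate(_COMPLEMENT)
            cls, gid = va.assign_variant(
                genes, genomes, regions,
                va.VariantSite(chrom, pos, ref_g, alt_g, status))
            want = ("synonymous" if silent else "nonsynonymous")
            if cls != want or gid != gene.gene_id:
                continue
            used_sites.add(pos)
            used_codons.add((gene.gene_id, ci))
            mk = ("PS" if silent else "PR") if status == "polymorphic" else (
                "FS" if silent else "FR")
            ledger_rows.append((chrom, pos, ref_g, alt_g, status, mk,
                                gene.gene_id))
            placed += 1
        if placed < count:
            raise _PlacementError(
                f"gene {gene.gene_id}: placed {placed}/{count} "
                f"{'silent' if silent else 'replacement'} variants")

    def place_regulatory(gene, status, count):
        region = region_by_gene.get(gene.gene_id)
        if region is None:
            if count:
                raise _PlacementError(
                    f"gene {gene.gene_id} has no upstream region")
            return
        sites = list(range(region.start, region.end))
        rng.shuffle(sites)
        placed = 0
        for pos in sites:
            if placed == count:
                break
            if pos in used_sites:
                continue
            ref_g = genome_str[pos]
            alt_g = str(rng.choice([b for b in "ACGT" if b != ref_g]))
            cls, gid = va.assign_variant(
                genes, genomes, regions,
                va.VariantSite(chrom, pos, ref_g, alt_g, status))
            if cls != "regulatory" or gid != gene.gene_id:
                continue
            used_sites.add(pos)
            mk = "PC" if status == "polymorphic" else "FC"
            ledger_rows.append((chrom, pos, ref_g, alt_g, status, mk,
                                gene.gene_id))
            placed += 1
        if placed < count:
            raise _PlacementError(
                f"gene {gene.gene_id}: placed {placed}/{count} regulatory "
                "variants")

    for gene, (_, row) in zip(genes, plan.iterrows()):
        place_coding(gene, silent=True, status="polymorphic", count=int(row["PS"]))
        place_coding(gene, silent=True, status="fixed", count=int(row["FS"]))
        place_coding(gene, silent=False, status="polymorphic", count=int(row["PR"]))
        place_coding(gene, silent=False, status="fixed", count=int(row["FR"]))
        place_regulatory(gene, "polymorphic", int(row["PC"]))
        place_regulatory(gene, "fixed", int(row["FC"]))

    ledger = pd.DataFrame(ledger_rows, columns=["chrom", "pos", "ref", "alt",
                                                "status", "mk_class",
                                                "gene_id"])
    ledger = ledger.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth.variant_ledger = ledger
    truth.genes = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "strand": [g.strand for g in genes],
        "cds_length": [sum(e - s for s, e in g.cds_intervals) for g in genes],
    })

    va.write_fasta(genomes, fasta)
    va.write_gff3(genes, gff)
    va.write_variant_table(
        ledger[["chrom", "pos", "ref", "alt", "status"]], var)
    truth_json = Path(var).with_name("truth.json")
    truth_json.write_text(json.dumps({
        "seed": int(truth.seed),
        "counts": plan.to_dict(orient="list"),
        "n_variants": int(len(ledger)),
    }, indent=1))
    return {"fasta": fasta, "gff3": gff, "variants": var, "truth": truth_json}
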