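"""Simulation of autotetraploid biparental breeding populations.

Emulates the data-generating setting of a mid-sized tetraploid potato
breeding program: eight biparental crosses descended from four shared
(grand)parents, array SNPs spread over 12 pseudomolecules plus small
unanchored groups ("00", "UN"), and a four-trait phenotype panel in which an
AUDPC-type late-blight susceptibility trait is negatively correlated with
tuber number.

Meiosis follows the simplest tetrasomic model: the four homologs pair as two
random bivalents (three pairings, equal probability), each bivalent yields
one recombinant chromatid with a Poisson number of crossovers placed by
Haldane's no-interference model, and there is no double reduction. Founder
LD is induced by building founder homologs as block mosaics of a small pool
of base haplotypes, which is cheap and gives the pruning module realistic,
distance-decaying r^2 structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .io import DosageMatrix
from .phenotypes import audpc as _audpc


def _default_h2():
    return {
        "tuber_number": 0.40,
        "tuber_weight_total": 0.35,
        "tuber_weight_avg": 0.35,
        "susceptibility": 0.45,
        "flowering_days": 0.50,
    }


@dataclass
class SimConfig:
    """Study-design parameters of the simulated breeding population.

    Defaults produce the genotyped subset of such a program: 8 families x 11
    offspring plus the 4 shared ancestors (n = 92), with ~5,100 SNPs over 12
    pseudomolecules and 2 unanchored groups. ``offspring_per_family`` may be
    a single int or one count per family (field populations run into the
    hundreds per cross).
    """

    n_families: int = 8
    offspring_per_family: int | tuple = 11
    n_chrom: int = 12
    unanchored_groups: tuple = ("00", "UN")
    loci_per_chrom: int = 420
    loci_per_unanchored: int = 40
    map_length_morgans: float = 0.9
    chrom_length_bp: int = 70_000_000
    founder_pool_size: int = 8
    founder_switch_prob: float = 0.08
    founder_alt_freq: tuple = (0.10, 0.90)
    n_qtl: int = 20
    qtl_effect_scale: float = 1.0
    qtl_effect_decay: float = 0.6
    h2: dict = field(default_factory=_default_h2)
    family_variance_share: float = 0.15
    trait_correlation: float = -0.467
    n_score_dates: int = 6
    missing_rate: float = 0.002
    frac_high_missing: float = 0.01
    frac_low_identity: float = 0.05
    frac_unmapped: float = 0.02
    flowering_missing_rate: float = 0.5
    double_reduction_rate: float = 0.0
    seed: int = 2025

    def __post_init__(self):
        if self.double_reduction_rate != 0.0:
            raise NotImplementedError(
                "double reduction is reserved for future use; rate must be 0"
            )
        for t, h in self.h2.items():
            if not (0.0 < h < 1.0):
                raise ValueError(f"h2[{t!r}] must be in (0, 1)")
        if self.n_families < 1 or self.loci_per_chrom < 1:
            raise ValueError("counts must be positive")

    @property
    def chrom_labels(self) -> list[str]:
        labels = [str(c) for c in range(1, self.n_chrom + 1)]
        return labels + list(self.unanchored_groups)

    def loci_for(self, chrom: str) -> int:
        if chrom in self.unanchored_groups:
            return self.loci_per_unanchored
        return self.loci_per_chrom

    def offspring_counts(self) -> list[int]:
        if isinstance(self.offspring_per_family, int):
            return [self.offspring_per_family] * self.n_families
        counts = list(self.offspring_per_family)
        if len(counts) != self.n_families:
            raise ValueError("offspring_per_family length != n_families")
        return counts


@dataclass
class PhasedTetraploid:
    """Four phased homologs per chromosome; dosage = allele sum."""

    homologs: dict  # chrom -> (4, n_loci) int8 array

    def dosages(self, chrom_order) -> np.ndarray:
        return np.concatenate(
            [self.homologs[c].sum(axis=0) for c in chrom_order]
        ).astype(float)


@dataclass
class GeneticMap:
    """Marker coordinates: bp positions and genetic positions (Morgans)."""

    marker_map: pd.DataFrame          # marker, chrom, pos_bp
    genetic_pos: dict                 # chrom -> positions in Morgans
    chrom_order: list


@dataclass
class SimResult:
    """Everything one simulated study produces."""

    config: SimConfig
    genotypes: DosageMatrix
    marker_map: pd.DataFrame
    metadata: pd.DataFrame
    identity: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# genome and founders
# ---------------------------------------------------------------------------

def make_genetic_map(cfg: SimConfig, rng: np.random.Generator) -> GeneticMap:
    rows, gpos = [], {}
    for chrom in cfg.chrom_labels:
        n = cfg.loci_for(chrom)
        length = (cfg.chrom_length_bp if chrom not in cfg.unanchored_groups
                  else cfg.chrom_length_bp // 10)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n,
                                 replace=False))
        morgans = (cfg.map_length_morgans
                   if chrom not in cfg.unanchored_groups
                   else cfg.map_length_morgans / 10.0)
        gpos[chrom] = pos / length * morgans
        tag = chrom if chrom in cfg.unanchored_groups else f"{int(chrom):02d}"
        for i, p in enumerate(pos):
            rows.append((f"snp_{tag}_{i:05d}", chrom, int(p)))
    mm = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"])
    return GeneticMap(mm, gpos, cfg.chrom_labels)


def _haplotype_pool(cfg: SimConfig, n_loci: int, rng) -> np.ndarray:
    lo, hi = cfg.founder_alt_freq
    p = rng.uniform(lo, hi, size=n_loci)
    return (rng.random((cfg.founder_pool_size, n_loci)) < p).astype(np.int8)


def _mosaic_homolog(pool: np.ndarray, switch_prob: float, rng) -> np.ndarray:
    n_hap, n_loci = pool.shape
    switches = rng.random(n_loci) < switch_prob
    switches[0] = True
    idx = np.zeros(n_loci, dtype=int)
    current = 0
    for l in range(n_loci):
        if switches[l]:
            current = rng.integers(n_hap)
        idx[l] = current
    return pool[idx, np.arange(n_loci)]


def simulate_founders(cfg: SimConfig, gmap: GeneticMap,
                      rng: np.random.Generator, n_founders: int
                      ) -> list[PhasedTetraploid]:
    """Draw unrelated tetraploid founders with block-mosaic LD."""
    pools = {c: _haplotype_pool(cfg, cfg.loci_for(c), rng)
             for c in gmap.chrom_order}
    founders = []
    for _ in range(n_founders):
        homologs = {}
        for c in gmap.chrom_order:
            homologs[c] = np.stack([
                _mosaic_homolog(pools[c], cfg.founder_switch_prob, rng)
                for _ in range(4)
            ])
        founders.append(PhasedTetraploid(homologs))
    return founders


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

_BIVALENT_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _recombinant_chromatid(ha, hb, genetic_pos, rng) -> np.ndarray:
    """One chromatid from a bivalent of homologs ha/hb (Haldane model)."""
    length = genetic_pos[-1] if len(genetic_pos) else 0.0
    n_co = rng.poisson(length)
    if n_co == 0:
        return (ha if rng.random() < 0.5 else hb).copy()
    breaks = np.sort(rng.uniform(0.0, length, size=n_co))
    phase = (np.searchsorted(breaks, genetic_pos)
             + rng.integers(2)) % 2
    return np.where(phase == 0, ha, hb).astype(np.int8)


def meiosis_gamete(parent: PhasedTetraploid, gmap: GeneticMap,
                   rng: np.random.Generator) -> dict:
    """A diploid gamete: two recombinant homologs per chromosome.

    The four homologs pair into two random bivalents (all three pairings
    equally likely); each bivalent contributes one recombinant chromatid.
    No double reduction.
    """
    gamete = {}
    for c in gmap.chrom_order:
        h = parent.homologs[c]
        pairing = _BIVALENT_PAIRINGS[rng.integers(3)]
        chromatids = [
            _recombinant_chromatid(h[a], h[b], gmap.genetic_pos[c], rng)
            for a, b in pairing
        ]
        gamete[c] = np.stack(chromatids)
    return gamete


def simulate_family(p1: PhasedTetraploid, p2: PhasedTetraploid,
                    n_offspring: int, gmap: GeneticMap,
                    rng: np.random.Generator) -> list[PhasedTetraploid]:
    """Biparental cross: each offspring unites one gamete from each parent."""
    offspring = []
    for _ in range(n_offspring):
        g1 = meiosis_gamete(p1, gmap, rng)
        g2 = meiosis_gamete(p2, gmap, rng)
        homologs = {c: np.concatenate([g1[c], g2[c]])
                    for c in gmap.chrom_order}
        offspring.append(PhasedTetraploid(homologs))
    return offspring


# ---------------------------------------------------------------------------
# population, traits, dataset
# ---------------------------------------------------------------------------

def simulate_population(cfg: SimConfig, rng=None):
    """Build the pedigree: 4 shared ancestors, 8 biparental families.

    Families 1-4 are crosses among the four ancestors; families 5-8 cross
    F1 individuals derived from them, so the ancestors are grandparents of
    those families. Genotyped samples = all offspring + the 4 ancestors.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gmap = make_genetic_map(cfg, rng)
    ancestors = simulate_founders(cfg, gmap, rng, 4)
    extra = simulate_founders(cfg, gmap, rng, max(cfg.n_families - 4, 0))

    anc_pairs = [(0, 1), (2, 3), (0, 2), (1, 3), (0, 3), (1, 2)]
    parents, parent_desc = [], []
    for f in range(cfg.n_families):
        if f < min(4, len(anc_pairs)):
            a, b = anc_pairs[f]
            parents.append((ancestors[a], ancestors[b]))
            parent_desc.append("ancestor-cross")
        else:
            a, b = anc_pairs[f % len(anc_pairs)]
            f1a = simulate_family(ancestors[a], ancestors[b], 1, gmap, rng)[0]
            other = extra[(f - 4) % len(extra)] if extra else ancestors[b]
            parents.append((f1a, other))
            parent_desc.append("grandparent-cross")

    counts = cfg.offspring_counts()
    samples, meta_rows, phased = [], [], []
    for f, (n_off, (p1, p2)) in enumerate(zip(counts, parents), start=1):
        fam = f"F{f}"
        for k, child in enumerate(simulate_family(p1, p2, n_off, gmap, rng)):
            sid = f"{fam}_{k + 1:03d}"
            samples.append(sid)
            meta_rows.append((sid, fam, "offspring"))
            phased.append(child)
    for a, anc in enumerate(ancestors, start=1):
        sid = f"ANC{a}"
        samples.append(sid)
        role = "parent" if a <= 4 else "grandparent"
        meta_rows.append((sid, "ancestor", role))
        phased.append(anc)

    dos = np.stack([ind.dosages(gmap.chrom_order) for ind in phased])

    # genotyping noise: sparse random missingness plus a few bad markers
    miss = rng.random(dos.shape) < cfg.missing_rate
    n_mark = dos.shape[1]
    n_bad = int(round(cfg.frac_high_missing * n_mark))
    bad = rng.choice(n_mark, size=n_bad, replace=False)
    for j in bad:
        k = rng.integers(11, max(12, dos.shape[0] // 3))
        rows = rng.choice(dos.shape[0], size=min(k, dos.shape[0]),
                          replace=False)
        miss[rows, j] = True
    dos = dos.astype(float)
    dos[miss] = np.nan

    genotypes = DosageMatrix(samples, list(gmap.marker_map["marker"]), dos,
                             ploidy=4)
    metadata = pd.DataFrame(meta_rows,
                            columns=["sample_id", "family", "role"])
    return genotypes, gmap, metadata, phased


def simulate_identity_table(cfg: SimConfig, marker_ids,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Probe-alignment identity per marker, BLAST-style best hits.

    Most probes align at 97-100% identity; a fraction fall below the 97%
    cutoff and a fraction are unmapped (absent from the table).
    """
    m = len(marker_ids)
    pident = rng.uniform(97.0, 100.0, size=m)
    n_low = int(round(cfg.frac_low_identity * m))
    low = rng.choice(m, size=n_low, replace=False)
    pident[low] = rng.uniform(80.0, 96.99, size=n_low)
    n_un = int(round(cfg.frac_unmapped * m))
    unmapped = set(rng.choice(m, size=n_un, replace=False))
    rows = [(mid, round(pi, 2)) for j, (mid, pi)
            in enumerate(zip(marker_ids, pident)) if j not in unmapped]
    return pd.DataFrame(rows, columns=["marker", "pident"])


def _standardize(x):
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def simulate_traits(genotypes: DosageMatrix, metadata: pd.DataFrame,
                    cfg: SimConfig, rng=None):
    """Simulate the four-trait panel plus flowering time.

    Each trait decomposes into an additive genetic value from ``n_qtl``
    marker loci, a family effect, and a residual, with variance shares set
    by ``h2`` and ``family_variance_share``. Tuber number borrows the
    susceptibility phenotype with coefficient ``trait_correlation`` so the
    realized susceptibility(AUDPC)-yield correlation lands near the target.
    Disease severity follows a logistic progress curve whose midpoint comes
    earlier for susceptible clones, scored at ``n_score_dates`` dates, and
    summarized as AUDPC by the trapezoidal rule.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = genotypes.n_samples
    d = genotypes.dosages
    dimp = d.copy()
    mu_m = np.nanmean(dimp, axis=0)
    nanmask = np.isnan(dimp)
    dimp[nanmask] = np.take(mu_m, np.nonzero(nanmask)[1])

    fam = metadata.set_index("sample_id").loc[genotypes.sample_ids, "family"]
    fam_labels = fam.unique()
    fam_eff = dict(zip(fam_labels, rng.normal(size=len(fam_labels))))
    fam_vec = _standardize(np.array([fam_eff[f] for f in fam]))

    c_f2 = cfg.family_variance_share

    def genetic_value(n_qtl, exclude=()):
        # geometric effect-size series: a few major QTL plus a polygenic
        # tail, the architecture typical of late-blight resistance
        poly = np.flatnonzero(np.nanstd(d, axis=0) > 0)
        poly = np.array([j for j in poly if j not in exclude])
        qtl = rng.choice(poly, size=min(n_qtl, len(poly)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(qtl))
        eff = (cfg.qtl_effect_scale * signs
               * cfg.qtl_effect_decay ** np.arange(len(qtl)))
        g = dimp[:, qtl] @ eff
        return _standardize(g), qtl, eff

    def compose(g, h2):
        c_g = np.sqrt((1 - c_f2) * h2)
        c_e = np.sqrt((1 - c_f2) * (1 - h2))
        return (c_g * g + np.sqrt(c_f2) * fam_vec
                + c_e * rng.normal(size=n))

    truth_qtl = []
    markers = np.array(genotypes.marker_ids)

    g_sus, qtl_s, eff_s = genetic_value(cfg.n_qtl)
    susceptibility = compose(g_sus, cfg.h2["susceptibility"])
    for j, a in zip(qtl_s, eff_s):
        truth_qtl.append(("susceptibility", markers[j], float(a)))

    # disease progress: logistic curves scored across the season
    dates = np.linspace(20.0, 80.0, cfg.n_score_dates)
    t50 = 55.0 - 12.0 * susceptibility
    sev = 100.0 / (1.0 + np.exp(-(dates[None, :] - t50[:, None]) / 7.0))
    audpc_vals = np.array([_audpc(dates, sev[i]) for i in range(n)])

    # tuber number: own genetics plus a calibrated share of the realized
    # AUDPC axis, orthogonalized so the phenotypic correlation lands on
    # the configured target (resistance-yield trade-off)
    rho = cfg.trait_correlation
    g_tn, qtl_tn, eff_tn = genetic_value(cfg.n_qtl, exclude=set(qtl_s))
    own = compose(g_tn, cfg.h2["tuber_number"])
    audpc_std = _standardize(audpc_vals)
    slope = np.cov(own, audpc_std)[0, 1] / max(audpc_std.var(), 1e-12)
    own_orth = _standardize(own - slope * audpc_std)
    tn_latent = rho * audpc_std + np.sqrt(1 - rho ** 2) * own_orth
    tuber_number = np.maximum(np.round(8.0 + 3.0 * tn_latent), 0.0)
    for j, a in zip(qtl_s, eff_s):
        truth_qtl.append(("tuber_number", markers[j], float(rho * a)))
    for j, a in zip(qtl_tn, eff_tn):
        truth_qtl.append(
            ("tuber_number", markers[j], float(np.sqrt(1 - rho ** 2) * a))
        )

    g_avg, qtl_avg, eff_avg = genetic_value(cfg.n_qtl)
    avg_latent = compose(g_avg, cfg.h2["tuber_weight_avg"])
    tuber_weight_avg = 90.0 + 20.0 * avg_latent
    for j, a in zip(qtl_avg, eff_avg):
        truth_qtl.append(("tuber_weight_avg", markers[j], float(a)))

    tuber_weight_total = (tuber_number * tuber_weight_avg / 1000.0
                          * (1.0 + 0.05 * rng.normal(size=n)))

    g_fl, qtl_fl, eff_fl = genetic_value(max(cfg.n_qtl // 4, 2))
    flowering = 45.0 + 5.0 * compose(g_fl, cfg.h2["flowering_days"])
    flowering[rng.random(n) < cfg.flowering_missing_rate] = np.nan
    for j, a in zip(qtl_fl, eff_fl):
        truth_qtl.append(("flowering_days", markers[j], float(a)))

    phenotypes = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "family": fam.to_numpy(),
        "tuber_number": tuber_number,
        "tuber_weight_total": np.round(tuber_weight_total, 3),
        "tuber_weight_avg": np.round(tuber_weight_avg, 2),
        "audpc": np.round(audpc_vals, 2),
        "flowering_days": flowering,
    })
    truth = {
        "qtl": pd.DataFrame(truth_qtl,
                            columns=["trait", "marker", "effect"]),
        "true_gebv": pd.DataFrame({
            "sample_id": genotypes.sample_ids,
            "susceptibility": g_sus,
            "tuber_number": rho * g_sus + np.sqrt(1 - rho ** 2) * g_tn,
            "tuber_weight_avg": g_avg,
            "flowering_days": g_fl,
        }),
        "severity_curves": sev,
        "score_dates": dates,
    }
    return phenotypes, truth


def simulate_dataset(cfg: SimConfig | None = None) -> SimResult:
    """One self-contained simulated study: genotypes, map, metadata,
    identity table, phenotypes, and truth tables."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genotypes, gmap, metadata, _ = simulate_population(cfg, rng)
    identity = simulate_identity_table(cfg, genotypes.marker_ids, rng)
    phenotypes, truth = simulate_traits(genotypes, metadata, cfg, rng)
    return SimResult(cfg, genotypes, gmap.marker_map, metadata, identity,
                     phenotypes, truth)


def write_dataset(sim: SimResult, out_dir) -> dict:
    """Write every component as plain text; re-readable by the io module."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.csv",
        "marker_map": out / "marker_map.tsv",
        "metadata": out / "sample_metadata.csv",
        "identity": out / "identity.tsv",
        "phenotypes": out / "phenotypes.csv",
        "truth_qtl": out / "truth_qtl.tsv",
        "truth_gebv": out / "truth_gebv.tsv",
        "config": out / "sim_config.yaml",
    }
    tio.write_genotypes(sim.genotypes, paths["genotypes"])
    tio.write_marker_map(sim.marker_map, paths["marker_map"])
    sim.metadata.to_csv(paths["metadata"], index=False)
    # identity written as 12-column BLAST outfmt 6
    with open(paths["identity"], "w") as fh:
        for _, row in sim.identity.iterrows():
            fh.write(f"{row['marker']}\tchr\t{row['pident']}\t100\t0\t0\t"
                     f"1\t100\t1\t100\t1e-50\t180\n")
    sim.phenotypes.to_csv(paths["phenotypes"], index=False)
    sim.truth["qtl"].to_csv(paths["truth_qtl"], sep="\t", index=False)
    sim.truth["true_gebv"].to_csv(paths["truth_gebv"], sep="\t", index=False)
    cfg = asdict(sim.config)
    cfg["unanchored_groups"] = list(sim.config.unanchored_groups)
    cfg["founder_alt_freq"] = list(sim.config.founder_alt_freq)
    if not isinstance(cfg["offspring_per_family"], int):
        cfg["offspring_per_family"] = list(cfg["offspring_per_family"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}


def read_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "unanchored_groups" in raw:
        raw["unanchored_groups"] = tuple(raw["unanchored_groups"])
    if "founder_alt_freq" in raw:
        raw["founder_alt_freq"] = tuple(raw["founder_alt_freq"])
    if isinstance(raw.get("offspring_per_family"), list):
        raw["offspring_per_family"] = tuple(raw["offspring_per_family"])
    return SimConfig(**raw)
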