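"""Synthetic paired miRNA/mRNA data with planted, recoverable structure.

The generator emulates the statistical shape of a divergent-RFI bulk
expression experiment: negative-binomial counts for miRNAs and mRNAs over
two groups of animals, correlated feature modules driven by per-module
latent Gaussian sample signals, hub miRNAs whose modules are anti-correlated
with designated mRNA target modules, a continuous RFI trait generated from
designated module signals (with a BLUP-like index used to split animals into
feed-efficient / feed-inefficient groups), planted differential miRNA
expression, 3'UTR sequences carrying exact seed sites for the planted
regulatory pairs, and gene sets (one per planted mRNA module plus random
decoys).  A :class:`TruthManifest` records everything planted so downstream
recovery can be scored.

All outputs are pure functions of ``(config, rng_seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rfinet.enrichment import GeneSetCollection, write_gmt
from rfinet.phenotypes import FEED_EFFICIENT, FEED_INEFFICIENT
from rfinet.targets import normalize_nt, reverse_complement

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic divergent-RFI dataset.

    The defaults describe a desk-scale version of the study design: 10
    animals per RFI group, ~150 expressed miRNAs, and a reduced mRNA
    transcriptome with planted co-expression modules of the sizes the mRNA
    network stage expects (30-60 genes; miRNA modules 8-16 features).
    ``within_module_cor`` is the target pairwise correlation of member
    log-expression (member loadings on the shared module latent are scaled
    against the NB measurement noise to achieve it; hubs use ``hub_cor``);
    ``coupling_strength`` (in [-1, 0]) is the correlation between a miRNA
    module's latent signal and its target mRNA module's latent signal.
    ``trait_linked_modules`` lists ``(data_type, module_index, effect)``
    triples feeding the simulated RFI.
    """

    n_samples_per_group: int = 10
    n_mirna: int = 150
    n_mrna: int = 1000
    n_mirna_modules: int = 4
    n_mrna_modules: int = 6
    mirna_module_size_range: tuple = (8, 16)
    module_size_range: tuple = (30, 60)  # mRNA module sizes
    within_module_cor: float = 0.8
    hub_cor: float = 0.95
    nb_mean_range: tuple = (50.0, 1000.0)
    nb_dispersion: float = 0.1
    n_hubs_per_module: int = 2
    n_targets_per_hub: int = 5
    coupling_strength: float = -0.8
    trait_linked_modules: list = field(
        default_factory=lambda: [("mirna", 1, 1.0)]
    )
    trait_noise_sd: float = 0.5
    n_de_mirna: int = 5
    de_log2fc: float = -1.0
    utr_length: int = 500
    seed_site_rate: float = 0.05
    n_decoy_sets: int = 20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 3:
            raise ValueError("need at least 3 samples per group")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in (0, 1)")
        if not -1.0 <= self.coupling_strength <= 0.0:
            raise ValueError("coupling_strength must be in [-1, 0]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ValueError("nb_mean_range must be positive and ordered")
        if self.utr_length < 8:
            raise ValueError("utr_length must be >= 8")
        for name, rng_, n_mod, n_feat in [
            ("miRNA", self.mirna_module_size_range, self.n_mirna_modules, self.n_mirna),
            ("mRNA", self.module_size_range, self.n_mrna_modules, self.n_mrna),
        ]:
            lo, hi = rng_
            if not (2 <= lo <= hi):
                raise ValueError(f"{name} module size range invalid")
            if n_mod * hi > n_feat:
                raise ValueError(
                    f"infeasible config: {n_mod} {name} modules of up to {hi} "
                    f"features exceed the {n_feat} available"
                )
        for dt, idx, _ in self.trait_linked_modules:
            n_mod = self.n_mirna_modules if dt == "mirna" else self.n_mrna_modules
            if dt not in ("mirna", "mrna") or not 0 <= idx < n_mod:
                raise ValueError(f"invalid trait-linked module ({dt}, {idx})")


@dataclass
class TruthManifest:
    """Everything planted by the generator, for downstream recovery scoring."""

    mirna_modules: dict = field(default_factory=dict)   # module id -> feature ids
    mrna_modules: dict = field(default_factory=dict)
    hubs: dict = field(default_factory=dict)            # miRNA module id -> hub ids
    regulatory_pairs: list = field(default_factory=list)  # (mirna_id, gene_id)
    coupled_module_pairs: list = field(default_factory=list)
    trait_linked: list = field(default_factory=list)    # (data_type, module id, effect)
    de_mirnas: dict = field(default_factory=dict)       # mirna id -> true log2fc

    def module_labels(self, data_type: str, feature_ids) -> pd.Series:
        """Planted module label per feature ('none' for background)."""
        modules = self.mirna_modules if data_type == "mirna" else self.mrna_modules
        lab = pd.Series("none", index=list(feature_ids), name="truth")
        for mod, members in modules.items():
            lab.loc[members] = mod
        return lab

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["regulatory_pairs"] = [tuple(p) for p in d["regulatory_pairs"]]
        d["coupled_module_pairs"] = [tuple(p) for p in d["coupled_module_pairs"]]
        d["trait_linked"] = [tuple(t) for t in d["trait_linked"]]
        return cls(**d)


def simulate_nb_counts(mean_matrix, dispersion: float, rng_seed) -> np.ndarray:
    """Independent NB draws with Var = mu + dispersion * mu^2.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.  At
    dispersion 0 the draws are Poisson.
    """
    mu = np.asarray(mean_matrix, dtype=float)
    if not np.all(np.isfinite(mu)) or (mu < 0).any():
        raise ValueError("means must be finite and nonnegative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def plant_utr_sites(
    pairs,
    mirna_seqs: dict,
    gene_ids,
    utr_length: int,
    seed_site_rate: float,
    rng_seed,
) -> dict:
    """Random-background 3'UTRs with target sites planted for the given pairs.

    Each regulated gene receives one full complementary site for its miRNA:
    the reverse complement of miRNA positions 2..L followed by an A (so the
    site contains an exact 8mer seed match and also supports a
    high-scoring complementarity alignment, the way a strong biological site
    with 3' supplementary pairing would).  Background genes additionally
    receive a decoy seed-only 8mer for a random miRNA with probability
    ``seed_site_rate``.
    """
    if utr_length < 8:
        raise ValueError("utr_length must be >= 8")
    for mid, _ in pairs:
        if len(normalize_nt(mirna_seqs[mid])) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    gene_ids = list(gene_ids)
    utrs = {
        g: "".join(rng.choice(_DNA, size=utr_length)) for g in gene_ids
    }
    by_gene: dict[str, list[str]] = {}
    for mid, gid in pairs:
        by_gene.setdefault(gid, []).append(mid)
    mir_ids = sorted(mirna_seqs)
    for gid in gene_ids:
        sites = []
        for mid in by_gene.get(gid, []):
            mir = normalize_nt(mirna_seqs[mid])
            sites.append(reverse_complement(mir[1:]) + "A")
        if gid not in by_gene and mir_ids and rng.random() < seed_site_rate:
            mid = mir_ids[rng.integers(len(mir_ids))]
            mir = normalize_nt(mirna_seqs[mid])
            sites.append(reverse_complement(mir[1:8]) + "A")  # seed-only 8mer
        utr = utrs[gid]
        for site in sites:
            if len(site) >= len(utr):
                utr = site[: len(utr)]
                continue
            pos = int(rng.integers(0, len(utr) - len(site) + 1))
            utr = utr[:pos] + site + utr[pos + len(site):]
        utrs[gid] = utr
    return utrs


def _draw_module_sizes(rng, n_modules, size_range):
    lo, hi = size_range
    return [int(rng.integers(lo, hi + 1)) for _ in range(n_modules)]


def _loading_for_cor(base_mean, dispersion, rho, rng=None, n_cal=256):
    """Loading on the module latent giving observed log-scale correlation rho.

    A member with log2-mean b + lambda*z and NB measurement noise of log-scale
    variance v shows pairwise correlation lambda^2 / (lambda^2 + v) with its
    peers, so lambda^2 = v * rho / (1 - rho).  The delta-method value
    v ~ (1/mu + alpha) / ln(2)^2 underestimates the realised noise at typical
    count levels, so when an ``rng`` is supplied v is measured by a short
    Monte-Carlo per feature: simulate counts over calibration draws of z,
    regress log2(count + 1) on z, and use the residual variance.
    """
    mu = np.atleast_1d(np.asarray(base_mean, dtype=float))
    v = (1.0 / mu + dispersion) / (np.log(2.0) ** 2)
    lam = np.sqrt(v * rho / (1.0 - rho))
    if rng is None:
        return lam
    z = rng.standard_normal(n_cal)
    zc = z - z.mean()
    denom = (zc**2).sum()
    for _ in range(2):
        log_mu = np.log2(mu)[:, None] + lam[:, None] * z[None, :]
        counts = simulate_nb_counts(2.0**log_mu, dispersion, rng)
        y = np.log2(counts + 1.0)
        slope = (y - y.mean(axis=1, keepdims=True)) @ zc / denom
        resid = y - y.mean(axis=1, keepdims=True) - slope[:, None] * z[None, :]
        v_hat = (resid**2).sum(axis=1) / (n_cal - 2)
        lam = np.sqrt(v_hat * rho / (1.0 - rho))
    return lam


def simulate_dataset(config: SimulationConfig):
    """Generate the full synthetic dataset.

    Returns ``(counts_mirna, counts_mrna, phenotypes, utr_seqs, mirna_seqs,
    gene_sets, truth)``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    (
        rng_latent, rng_sig_mir, rng_sig_mrna, rng_base, rng_counts_mir,
        rng_counts_mrna, rng_seq, rng_phen, rng_sets, rng_pairs,
    ) = [np.random.default_rng(s) for s in ss.spawn(10)]

    n = 2 * config.n_samples_per_group
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    mirna_ids = [f"mir{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_mrna)]

    truth = TruthManifest()

    # module latent signals; coupled mRNA modules share (negatively) the
    # latent of the same-index miRNA module
    z_mir = [rng_latent.normal(size=n) for _ in range(config.n_mirna_modules)]
    z_mrna = []
    c = config.coupling_strength
    n_coupled = min(config.n_mirna_modules, config.n_mrna_modules)
    for m in range(config.n_mrna_modules):
        if m < n_coupled and c != 0.0:
            w = rng_latent.normal(size=n)
            z_mrna.append(c * z_mir[m] + np.sqrt(1.0 - c**2) * w)
            truth.coupled_module_pairs.append(
                (f"mirna_module_{m}", f"mrna_module_{m}", c)
            )
        else:
            z_mrna.append(rng_latent.normal(size=n))

    # phenotypes: RFI from the designated module latents, BLUP a noisy index
    # of the same genetic signal; groups = BLUP tails
    signal = np.zeros(n)
    for dt, idx, effect in config.trait_linked_modules:
        z = z_mir[idx] if dt == "mirna" else z_mrna[idx]
        signal += effect * z
        truth.trait_linked.append((dt, f"{dt}_module_{idx}", float(effect)))
    rfi = signal + rng_phen.normal(scale=config.trait_noise_sd, size=n)
    blup = 0.5 * signal + rng_phen.normal(scale=0.5, size=n)
    order = np.argsort(blup, kind="mergesort")
    group = np.empty(n, dtype=object)
    group[order[: config.n_samples_per_group]] = FEED_EFFICIENT
    group[order[config.n_samples_per_group:]] = FEED_INEFFICIENT
    phen = pd.DataFrame(
        {
            "animal_id": sample_ids,
            "group": group,
            "blup": np.round(0.08 * blup, 4),
            "rfi": np.round(rfi, 4),
            "imf": np.round(rng_phen.normal(3.0, 0.6, size=n), 2),
            "rea": np.round(rng_phen.normal(58.0, 6.0, size=n), 2),
        }
    )
    efficient = group == FEED_EFFICIENT

    # log2 mean matrices: module members share their module latent exactly,
    # member log-means = baseline + loading * latent, loading scaled so the
    # observed log-scale within-module correlation matches within_module_cor
    def build_log_means(n_feat, ids, sizes, latents, rng_jit, data_type,
                        n_hubs=0):
        lo, hi = config.nb_mean_range
        base_log2 = rng_base.uniform(np.log2(lo), np.log2(hi), size=n_feat)
        log_mu = np.tile(base_log2[:, None], (1, n))
        modules, hubs = {}, {}
        pos = 0
        hub_rho = max(config.within_module_cor, config.hub_cor)
        for m, size in enumerate(sizes):
            members = ids[pos: pos + size]
            rho = np.full(size, config.within_module_cor)
            rho[: min(n_hubs, size)] = hub_rho  # hubs: tightest latent tie
            lam = _loading_for_cor(2.0 ** base_log2[pos: pos + size],
                                   config.nb_dispersion, rho, rng=rng_jit)
            lam = lam * rng_jit.uniform(0.98, 1.02, size=size)
            log_mu[pos: pos + size] += lam[:, None] * latents[m][None, :]
            mod_id = f"{data_type}_module_{m}"
            modules[mod_id] = list(members)
            if n_hubs:
                hubs[mod_id] = list(members[: min(n_hubs, size)])
            pos += size
        return log_mu, modules, hubs, pos

    mir_sizes = _draw_module_sizes(rng_latent, config.n_mirna_modules,
                                   config.mirna_module_size_range)
    mrna_sizes = _draw_module_sizes(rng_latent, config.n_mrna_modules,
                                    config.module_size_range)
    log_mu_mir, truth.mirna_modules, truth.hubs, mir_used = build_log_means(
        config.n_mirna, mirna_ids, mir_sizes, z_mir, rng_sig_mir, "mirna",
        n_hubs=config.n_hubs_per_module,
    )
    log_mu_mrna, truth.mrna_modules, _, _ = build_log_means(
        config.n_mrna, gene_ids, mrna_sizes, z_mrna, rng_sig_mrna, "mrna"
    )

    # planted differential expression on background miRNAs
    background = [i for i in range(config.n_mirna) if i >= mir_used]
    n_de = min(config.n_de_mirna, len(background))
    de_rows = background[:n_de]
    for i in de_rows:
        log_mu_mir[i, efficient] += config.de_log2fc
        truth.de_mirnas[mirna_ids[i]] = float(config.de_log2fc)

    counts_mir = pd.DataFrame(
        simulate_nb_counts(2.0 ** log_mu_mir, config.nb_dispersion, rng_counts_mir),
        index=pd.Index(mirna_ids, name="feature_id"), columns=sample_ids,
    )
    counts_mrna = pd.DataFrame(
        simulate_nb_counts(2.0 ** log_mu_mrna, config.nb_dispersion, rng_counts_mrna),
        index=pd.Index(gene_ids, name="feature_id"), columns=sample_ids,
    )

    # sequences: mature miRNAs (RNA alphabet) and UTRs with planted sites
    mirna_seqs = {
        mid: "".join(rng_seq.choice(_RNA, size=22)) for mid in mirna_ids
    }
    for m, (mir_mod, mrna_mod, _) in enumerate(truth.coupled_module_pairs):
        genes = truth.mrna_modules[mrna_mod]
        for hub in truth.hubs[mir_mod]:
            k = min(config.n_targets_per_hub, len(genes))
            chosen = rng_pairs.choice(len(genes), size=k, replace=False)
            for gi in sorted(chosen):
                truth.regulatory_pairs.append((hub, genes[gi]))
    utr_seqs = plant_utr_sites(
        truth.regulatory_pairs, mirna_seqs, gene_ids,
        config.utr_length, config.seed_site_rate, rng_seq,
    )

    # gene sets: one per planted mRNA module plus random decoys
    gene_sets = GeneSetCollection()
    for mod, members in truth.mrna_modules.items():
        gene_sets.add(f"set_{mod}", members, f"planted members of {mod}")
    for d in range(config.n_decoy_sets):
        size = int(rng_sets.integers(30, 81))
        members = rng_sets.choice(len(gene_ids), size=size, replace=False)
        gene_sets.add(
            f"decoy_set_{d + 1:02d}",
            [gene_ids[i] for i in sorted(members)],
            "random decoy set",
        )

    return counts_mir, counts_mrna, phen, utr_seqs, mirna_seqs, gene_sets, truth


def write_dataset(outdir, counts_mir, counts_mrna, phen, utr_seqs, mirna_seqs,
                  gene_sets, truth) -> None:
    """Write all generated artifacts as plain-text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts_mir.to_csv(out / "counts_mirna.tsv", sep="\t")
    counts_mrna.to_csv(out / "counts_mrna.tsv", sep="\t")
    phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    _write_fasta(out / "utrs.fasta", utr_seqs)
    _write_fasta(out / "mirnas.fasta", mirna_seqs)
    write_gmt(gene_sets, out / "gene_sets.gmt")
    truth.to_json(out / "truth.json")


def _write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")
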