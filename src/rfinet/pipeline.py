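"""End-to-end orchestration of the integrative miRNA-mRNA RFI analysis.

Stage order per RFI group: count filtering and normalization -> co-expression
networks (miRNA and mRNA separately) -> module eigengenes -> module-trait
(RFI) correlation -> cross-omics ME correlation with negative-pair selection
-> hub miRNA selection -> hub-target / mRNA-module overlap -> ORA of overlap
gene lists.  Across groups: NB differential miRNA expression on the extreme
subset, target prediction for DE and hub miRNAs, ORA of DE-miRNA targets.
Every stage writes a TSV; a JSON run manifest records package version,
parameters and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

import rfinet
from rfinet import coexpression as cx
from rfinet import enrichment as enr
from rfinet import integration as integ
from rfinet import preprocess as pre
from rfinet.diffexpr import NegativeBinomialDE
from rfinet.phenotypes import FEED_EFFICIENT, FEED_INEFFICIENT, read_phenotypes
from rfinet.targets import AlignmentParams, TargetSet, predict_targets_from_sequences

log = logging.getLogger("rfinet")


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one tissue's run."""

    counts_mirna: str
    counts_mrna: str
    phenotypes: str
    mirna_fasta: str
    utr_fasta: str
    gene_sets: str
    outdir: str
    tissue: str = "tissue"
    truth_manifest: str | None = None
    max_zero_fraction: float = 0.2
    de_n_extreme: int = 4
    de_fdr: float = 0.10
    mirna_min_module_size: int = 5
    mrna_min_module_size: int = 30
    beta: int = 6
    signed: bool = False
    merge_height: float = 0.25
    detection: str = "hybrid"
    trait_alpha: float = 0.10
    cross_alpha: float = 0.10
    n_hubs: int = 5
    target_mode: str = "intersection"
    alignment_threshold: float = 80.0
    ora_fdr: float = 0.10
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def network_params(self, data_type: str) -> cx.NetworkParams:
        size = (
            self.mirna_min_module_size
            if data_type == "mirna"
            else self.mrna_min_module_size
        )
        return cx.NetworkParams(
            beta=self.beta,
            signed=self.signed,
            min_module_size=size,
            merge_height=self.merge_height,
            detection=self.detection,
        )


@dataclass
class GroupResult:
    """Per-RFI-group network and integration outputs."""

    group: str
    mirna_network: cx.CoexpressionResult
    mrna_network: cx.CoexpressionResult
    me_trait_mirna: pd.DataFrame
    me_trait_mrna: pd.DataFrame
    cross_me: pd.DataFrame
    hubs: dict
    overlaps: dict
    overlap_ora: dict


@dataclass
class PipelineResult:
    config: PipelineConfig
    phenotypes: pd.DataFrame
    de_table: pd.DataFrame
    de_significant: pd.DataFrame
    targets: TargetSet
    de_target_ora: pd.DataFrame
    groups: dict = field(default_factory=dict)


def _read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _prepare_network_input(counts: pd.DataFrame, samples, max_zero_fraction):
    sub = pre.filter_counts(counts[list(samples)], max_zero_fraction)
    s = pre.size_factors(sub)
    norm = pre.normalize_counts(sub, s)
    logx, kept = pre.log_transform_for_network(norm)
    return logx[kept], norm


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the result directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")

    stage = "load inputs"
    try:
        counts_mir = pre.read_counts(config.counts_mirna)
        counts_mrna = pre.read_counts(config.counts_mrna)
        phen = read_phenotypes(config.phenotypes)
        phen.index = pd.Index(phen["animal_id"].to_numpy())
        mirna_seqs = _read_fasta(config.mirna_fasta)
        utr_seqs = _read_fasta(config.utr_fasta)
        gene_sets = enr.read_gmt(config.gene_sets)
        log.info(
            "loaded %d miRNAs x %d samples, %d genes x %d samples, %d gene sets",
            *counts_mir.shape, *counts_mrna.shape, len(gene_sets),
        )

        # -- differential expression on the extreme subset -------------------
        stage = "differential expression"
        de_samples = _extreme_subset(phen, config.de_n_extreme)
        de_counts = pre.filter_counts(
            counts_mir[de_samples.index], config.max_zero_fraction
        )
        log.info(
            "DE on %d vs %d extreme samples; %d of %d miRNAs pass the filter",
            config.de_n_extreme, config.de_n_extreme,
            de_counts.shape[0], counts_mir.shape[0],
        )
        de_norm = pre.normalize_counts(de_counts, pre.size_factors(de_counts))
        de_res = NegativeBinomialDE(de_norm, de_samples["group"]).fit()
        de_sig = de_res.significant(config.de_fdr)
        log.info("%d DE miRNAs at FDR %g", len(de_sig), config.de_fdr)
        de_res.table.to_csv(out / "de_mirna.tsv", sep="\t")

        # -- per-group networks + integration ---------------------------------
        expressed_genes = pre.filter_counts(
            counts_mrna, config.max_zero_fraction
        ).index
        groups = {}
        for group in (FEED_EFFICIENT, FEED_INEFFICIENT):
            stage = f"network construction ({group})"
            groups[group] = _run_group(
                config, group, phen, counts_mir, counts_mrna, mirna_seqs,
                utr_seqs, expressed_genes, out,
            )

        # -- target prediction for DE + hub miRNAs ----------------------------
        stage = "target prediction"
        wanted = set(de_sig.index)
        for g in groups.values():
            for hub_list in g.hubs.values():
                wanted.update(hub_list)
        seqs = {m: mirna_seqs[m] for m in sorted(wanted) if m in mirna_seqs}
        params = AlignmentParams(score_threshold=config.alignment_threshold)
        targets = predict_targets_from_sequences(
            seqs, utr_seqs, expressed_genes, mode=config.target_mode,
            params=params,
        )
        log.info(
            "targets predicted for %d miRNAs (%d pairs)",
            len(targets.targets), len(targets.evidence),
        )
        targets.evidence.to_csv(out / "targets.tsv", sep="\t", index=False)

        # -- overlap ORA per group, DE-target ORA ------------------------------
        stage = "enrichment"
        for group, g in groups.items():
            g.overlaps = integ.hub_target_module_overlap(
                g.hubs, targets, g.mrna_network.assignment, g.cross_me
            )
            _write_overlaps(out, group, g.overlaps)
            universe = set(
                g.mrna_network.assignment[
                    g.mrna_network.assignment != cx.GREY
                ].index
            )
            g.overlap_ora = {}
            for pair, genes in g.overlaps.items():
                if not genes:
                    continue
                g.overlap_ora[pair] = enr.ora_hypergeometric(
                    genes, gene_sets, universe, config.ora_fdr
                )
            _write_pair_ora(out, group, g.overlap_ora)

        de_genes = sorted(
            {gene for m in de_sig.index for gene in targets.genes(m)}
        )
        de_ora = enr.ora_hypergeometric(
            de_genes, gene_sets, set(expressed_genes), config.ora_fdr
        )
        de_ora.to_csv(out / "de_target_ora.tsv", sep="\t", index=False)

        stage = "network export"
        for group, g in groups.items():
            edges = export_network_edges(g.hubs, g.overlaps, g.overlap_ora)
            edges.to_csv(out / f"edges_{group}.tsv", sep="\t", index=False)

        if config.truth_manifest:
            stage = "recovery report"
            _write_recovery(
                config, out, groups, de_res.table, targets, expressed_genes
            )

        _write_manifest(config, out)
    except Exception as exc:
        log.error("pipeline aborted at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(
        config=config,
        phenotypes=phen,
        de_table=de_res.table,
        de_significant=de_sig,
        targets=targets,
        de_target_ora=de_ora,
        groups=groups,
    )


def _run_group(config, group, phen, counts_mir, counts_mrna, mirna_seqs,
               utr_seqs, expressed_genes, out: Path) -> GroupResult:
    samples = phen.loc[phen["group"] == group, "animal_id"]
    nets = {}
    for data_type, counts in (("mirna", counts_mir), ("mrna", counts_mrna)):
        logx, _ = _prepare_network_input(
            counts, samples, config.max_zero_fraction
        )
        net = cx.CoexpressionNetwork(logx, config.network_params(data_type))
        res = net.fit()
        log.info(
            "%s %s network: %d modules, %d/%d features assigned",
            group, data_type, len(res.modules),
            int((res.assignment != cx.GREY).sum()), len(res.assignment),
        )
        res.to_tsv(
            out / f"modules_{data_type}_{group}.tsv",
            out / f"eigengenes_{data_type}_{group}.tsv",
        )
        nets[data_type] = res

    rfi = phen.loc[samples, "rfi"]
    me_trait = {}
    for data_type in ("mirna", "mrna"):
        me_trait[data_type] = integ.module_trait_correlation(
            nets[data_type].eigengenes, rfi, config.trait_alpha
        )
        me_trait[data_type].to_csv(
            out / f"me_trait_{data_type}_{group}.tsv", sep="\t", index=False
        )
        log.info(
            "%s %s: %d/%d modules correlated with RFI at p<%g",
            group, data_type, int(me_trait[data_type]["selected"].sum()),
            len(me_trait[data_type]), config.trait_alpha,
        )

    cross = integ.cross_me_correlation(
        nets["mirna"].eigengenes, nets["mrna"].eigengenes, config.cross_alpha
    )
    cross.to_csv(out / f"cross_me_{group}.tsv", sep="\t", index=False)
    log.info(
        "%s: %d negative miRNA-mRNA module pairs selected at p<%g",
        group, int(cross["selected"].sum()), config.cross_alpha,
    )

    hubs = integ.select_hub_mirnas(
        nets["mirna"].module_membership, nets["mirna"].assignment, config.n_hubs
    )
    pd.DataFrame(
        [(m, h) for m, lst in hubs.items() for h in lst],
        columns=["module", "mirna_id"],
    ).to_csv(out / f"hubs_{group}.tsv", sep="\t", index=False)

    return GroupResult(
        group=group,
        mirna_network=nets["mirna"],
        mrna_network=nets["mrna"],
        me_trait_mirna=me_trait["mirna"],
        me_trait_mrna=me_trait["mrna"],
        cross_me=cross,
        hubs=hubs,
        overlaps={},
        overlap_ora={},
    )


def _extreme_subset(phen: pd.DataFrame, n_per_tail: int) -> pd.DataFrame:
    """The n most extreme animals per tail, ranked by BLUP within group."""
    eff = phen[phen["group"] == FEED_EFFICIENT].sort_values(
        ["blup", "animal_id"], kind="mergesort"
    )
    ineff = phen[phen["group"] == FEED_INEFFICIENT].sort_values(
        ["blup", "animal_id"], kind="mergesort", ascending=[False, True]
    )
    if len(eff) < n_per_tail or len(ineff) < n_per_tail:
        raise ValueError("not enough animals for the extreme DE subset")
    return pd.concat([eff.iloc[:n_per_tail], ineff.iloc[:n_per_tail]])


def export_network_edges(hubs: dict, overlaps: dict, overlap_ora: dict) -> pd.DataFrame:
    """Cytoscape-importable edge list linking hubs, genes and enriched sets.

    Edge types: hub miRNA -> overlap gene (``targets``), overlap gene ->
    mRNA module (``member_of``), overlap gene list -> significantly enriched
    set (``enriched_in``, one edge per overlap gene in the set).
    """
    rows = []
    for (mir_mod, mrna_mod), genes in overlaps.items():
        hub_list = hubs.get(mir_mod, [])
        for g in genes:
            for h in hub_list:
                rows.append((h, g, "targets"))
            rows.append((g, mrna_mod, "member_of"))
        ora = overlap_ora.get((mir_mod, mrna_mod))
        if ora is None or len(ora) == 0:
            continue
        for _, srow in ora[ora["significant"]].iterrows():
            for g in genes:
                rows.append((g, srow["set"], "enriched_in"))
    df = pd.DataFrame(rows, columns=["source", "target", "edge_type"])
    return df.drop_duplicates().reset_index(drop=True)


def _write_overlaps(out: Path, group: str, overlaps: dict) -> None:
    rows = [
        (mir_mod, mrna_mod, g)
        for (mir_mod, mrna_mod), genes in overlaps.items()
        for g in genes
    ]
    pd.DataFrame(
        rows, columns=["mirna_module", "mrna_module", "gene_id"]
    ).to_csv(out / f"overlap_genes_{group}.tsv", sep="\t", index=False)


def _write_pair_ora(out: Path, group: str, overlap_ora: dict) -> None:
    frames = []
    for (mir_mod, mrna_mod), df in overlap_ora.items():
        df = df.copy()
        df.insert(0, "mirna_module", mir_mod)
        df.insert(1, "mrna_module", mrna_mod)
        frames.append(df)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["mirna_module", "mrna_module", "set", "description",
                     "N", "K", "n", "k", "pvalue", "qvalue", "significant"]
        )
    )
    combined.to_csv(out / f"overlap_ora_{group}.tsv", sep="\t", index=False)


def _write_recovery(config, out: Path, groups, de_table, targets,
                    expressed_genes) -> None:
    from rfinet import recovery as rec
    from rfinet.simulate import TruthManifest

    truth = TruthManifest.from_json(config.truth_manifest)
    report: dict = {"groups": {}}
    for group, g in groups.items():
        report["groups"][group] = {
            "mirna_modules": rec.module_recovery(g.mirna_network, truth, "mirna"),
            "mrna_modules": rec.module_recovery(g.mrna_network, truth, "mrna"),
            "coupled_pairs": rec.coupled_pair_recovery(
                g.cross_me, g.mirna_network, g.mrna_network, truth
            ),
            "trait_modules": {
                dt: rec.trait_module_recovery(
                    g.me_trait_mirna if dt == "mirna" else g.me_trait_mrna,
                    g.mirna_network if dt == "mirna" else g.mrna_network,
                    truth, dt,
                )
                for dt in ("mirna", "mrna")
            },
        }
    report["de"] = rec.de_recovery(de_table, truth, config.de_fdr)
    report["targets"] = rec.target_recovery(targets, truth, expressed_genes)
    with open(out / "recovery.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    log.info("recovery report written")


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    inputs = {}
    for name in ("counts_mirna", "counts_mrna", "phenotypes", "mirna_fasta",
                 "utr_fasta", "gene_sets"):
        path = getattr(config, name)
        inputs[name] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {
        "rfinet_version": rfinet.__version__,
        "parameters": dataclasses.asdict(config),
        "inputs": inputs,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(logfile)
        for h in log.handlers
    ):
        handler = logging.FileHandler(logfile, mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
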