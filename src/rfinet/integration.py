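"""Module-trait correlation, cross-omics module coupling, hubs and overlaps.

Links the per-group co-expression networks to the phenotype and to each
other: Pearson correlation of module eigengenes (MEs) with RFI (modules with
p < 0.10 are trait-associated), the full bipartite correlation of miRNA MEs
against mRNA MEs (pairs with negative correlation and p < 0.10 are candidate
regulatory module pairs), hub miRNA selection by top module membership (kME),
and the overlap of hub-miRNA target genes with the member genes of the
correlated mRNA module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from rfinet.coexpression import Eigengenes, GREY
from rfinet.targets import TargetSet


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t transform.

    t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom; |r| = 1 gives
    p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def module_trait_correlation(
    eigengenes: Eigengenes,
    trait: pd.Series,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Correlate each module eigengene with a trait (e.g. RFI).

    Samples are matched by id; missing trait values are dropped pairwise with
    n adjusted.  Modules with fewer than 3 complete pairs are skipped with a
    warning.  ``selected`` flags p < alpha.
    """
    trait = pd.Series(trait, dtype=float)
    samples = eigengenes.profiles.columns
    missing = [s for s in samples if s not in trait.index]
    if missing:
        raise ValueError(f"trait missing for samples: {missing[:5]}")
    rows = []
    for mod in eigengenes.modules():
        me = eigengenes.profiles.loc[mod]
        ok = trait.loc[samples].notna().to_numpy()
        n = int(ok.sum())
        if n < 3:
            warnings.warn(f"module {mod}: fewer than 3 complete pairs, skipped")
            continue
        r = _pearson(me.to_numpy()[ok], trait.loc[samples].to_numpy()[ok])
        p = correlation_p(r, n)
        rows.append({"module": mod, "r": r, "p": p, "n": n, "selected": p < alpha})
    return pd.DataFrame(rows, columns=["module", "r", "p", "n", "selected"])


def cross_me_correlation(
    mirna_eigengenes: Eigengenes,
    mrna_eigengenes: Eigengenes,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Full bipartite miRNA-ME x mRNA-ME Pearson correlation table.

    ``selected`` requires strictly negative correlation and p < alpha,
    reflecting the canonical repressive (negative) miRNA-target coupling.
    """
    a, b = mirna_eigengenes.profiles, mrna_eigengenes.profiles
    if list(a.columns) != list(b.columns):
        raise ValueError("eigengene sample ids do not match")
    n = a.shape[1]
    rows = []
    for mi in a.index:
        for mj in b.index:
            r = _pearson(a.loc[mi].to_numpy(), b.loc[mj].to_numpy())
            p = correlation_p(r, n)
            rows.append(
                {
                    "mirna_module": mi,
                    "mrna_module": mj,
                    "r": r,
                    "p": p,
                    "selected": (r < 0) and (p < alpha),
                }
            )
    return pd.DataFrame(
        rows, columns=["mirna_module", "mrna_module", "r", "p", "selected"]
    )


def select_hub_mirnas(
    module_membership: pd.DataFrame,
    assignment: pd.Series,
    k: int = 5,
    absolute: bool = False,
) -> dict:
    """Top-k hub miRNAs per module by module membership (kME).

    Members of each module are ranked by their kME toward that module's own
    eigengene, descending (signed by default, |kME| with ``absolute=True``);
    ties break by feature id ascending.  Modules smaller than k return all
    members.
    """
    assignment = assignment.loc[module_membership.index]
    hubs: dict[str, list[str]] = {}
    for mod in module_membership.columns:
        members = assignment[assignment == mod].index
        if len(members) == 0:
            continue
        mm = module_membership.loc[members, mod]
        if absolute:
            mm = mm.abs()
        ranked = sorted(members, key=lambda f: (-mm[f], f))
        hubs[mod] = ranked[: min(k, len(ranked))]
    return hubs


def hub_target_module_overlap(
    hubs: dict,
    targets: TargetSet,
    mrna_assignment: pd.Series,
    selected_pairs: pd.DataFrame,
) -> dict:
    """Targets of a miRNA module's hubs found inside its correlated mRNA module.

    For each selected cross-module pair, takes the union of predicted target
    genes of the miRNA module's hub miRNAs and intersects it with the member
    genes of the mRNA module.  Returns ``(mirna_module, mrna_module) ->
    sorted gene list`` (possibly empty).
    """
    overlaps: dict[tuple, list] = {}
    sel = selected_pairs[selected_pairs["selected"]] if "selected" in selected_pairs else selected_pairs
    for _, row in sel.iterrows():
        mir_mod, mrna_mod = row["mirna_module"], row["mrna_module"]
        hub_ids = hubs.get(mir_mod, [])
        union: set = set()
        for h in hub_ids:
            union |= set(targets.genes(h))
        module_genes = set(mrna_assignment[mrna_assignment == mrna_mod].index)
        overlaps[(mir_mod, mrna_mod)] = sorted(union & module_genes)
    return overlaps
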