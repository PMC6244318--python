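"""Scoring of pipeline output against a synthetic-data truth manifest."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from rfinet.coexpression import GREY, CoexpressionResult
from rfinet.simulate import TruthManifest
from rfinet.targets import TargetSet


def module_recovery(
    network: CoexpressionResult, truth: TruthManifest, data_type: str
) -> dict:
    """ARI of the inferred module assignment against the planted one.

    The ARI is computed over non-grey features (background features pulled
    into a module count against it); ``grey_rate`` is the fraction of planted
    module members left unassigned.
    """
    assignment = network.assignment
    truth_labels = truth.module_labels(data_type, assignment.index)
    non_grey = assignment[assignment != GREY]
    ari = (
        float(adjusted_rand_score(truth_labels.loc[non_grey.index], non_grey))
        if len(non_grey)
        else 0.0
    )
    planted = truth_labels[truth_labels != "none"].index
    grey_rate = (
        float((assignment.loc[planted] == GREY).mean()) if len(planted) else 0.0
    )
    return {
        "ari": ari,
        "grey_rate_planted": grey_rate,
        "n_modules": len(network.modules),
        "n_planted_modules": len(
            truth.mirna_modules if data_type == "mirna" else truth.mrna_modules
        ),
    }


def de_recovery(de_table: pd.DataFrame, truth: TruthManifest, fdr: float = 0.10) -> dict:
    """Sensitivity/false positives of the DE call against planted DE miRNAs."""
    tested = set(de_table.index)
    planted = [m for m in truth.de_mirnas if m in tested]
    called = set(de_table.index[de_table["qvalue"] < fdr])
    tp = sum(1 for m in planted if m in called)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "n_false": len(called - set(planted)),
    }


def target_recovery(targets: TargetSet, truth: TruthManifest, expressed) -> dict:
    """Fraction of planted regulatory pairs (expressed genes) predicted."""
    expressed = set(expressed)
    planted = [
        (m, g) for (m, g) in truth.regulatory_pairs if g in expressed
    ]
    predicted = targets.pairs()
    tp = sum(1 for p in planted if p in predicted)
    return {
        "n_planted_expressed": len(planted),
        "n_recovered": tp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
    }


def coupled_pair_recovery(
    cross_me: pd.DataFrame,
    mirna_network: CoexpressionResult,
    mrna_network: CoexpressionResult,
    truth: TruthManifest,
) -> dict:
    """Is each planted coupled module pair among the selected negative pairs?

    A planted (miRNA module, mRNA module) coupling counts as recovered when
    the inferred modules that best match the planted ones (by member overlap)
    form a selected pair in the cross-ME table.
    """
    results = []
    for mir_mod, mrna_mod, coupling in truth.coupled_module_pairs:
        inferred_mir = _best_match(
            mirna_network, truth.mirna_modules[mir_mod]
        )
        inferred_mrna = _best_match(
            mrna_network, truth.mrna_modules[mrna_mod]
        )
        recovered = False
        if inferred_mir is not None and inferred_mrna is not None:
            row = cross_me[
                (cross_me["mirna_module"] == inferred_mir)
                & (cross_me["mrna_module"] == inferred_mrna)
            ]
            recovered = bool(len(row)) and bool(row["selected"].iloc[0])
        results.append(
            {
                "planted_pair": (mir_mod, mrna_mod),
                "coupling": coupling,
                "recovered": recovered,
            }
        )
    frac = (
        float(np.mean([r["recovered"] for r in results])) if results else float("nan")
    )
    return {"pairs": results, "fraction_recovered": frac}


def trait_module_recovery(
    me_trait: pd.DataFrame,
    network: CoexpressionResult,
    truth: TruthManifest,
    data_type: str,
) -> dict:
    """Are the trait-linked planted modules among the p<alpha selections?"""
    planted_mods = (
        truth.mirna_modules if data_type == "mirna" else truth.mrna_modules
    )
    results = []
    for dt, mod_id, effect in truth.trait_linked:
        if dt != data_type:
            continue
        inferred = _best_match(network, planted_mods[mod_id])
        selected = False
        if inferred is not None:
            row = me_trait[me_trait["module"] == inferred]
            selected = bool(len(row)) and bool(row["selected"].iloc[0])
        results.append(
            {"planted_module": mod_id, "effect": effect, "selected": selected}
        )
    return {"modules": results}


def _best_match(network: CoexpressionResult, planted_members) -> str | None:
    """Inferred module capturing the largest share of the planted members."""
    members = [f for f in planted_members if f in network.assignment.index]
    if not members:
        return None
    labels = network.assignment.loc[members]
    labels = labels[labels != GREY]
    if labels.empty:
        return None
    return labels.value_counts().index[0]
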