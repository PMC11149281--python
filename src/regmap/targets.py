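"""Call drug-targeted risk enhancer-gene pairs.

Integrates three upstream tables: differential expression per treatment
(vs the stimulated non-treated arm), differential accessibility of the
elements, and the risk-locus / enhancer overlap table.  A call is emitted
for every (treatment, element, gene, locus) where the linked gene is
significantly modulated by the treatment and the element overlaps a risk
locus; the call is flagged direction-consistent when both the expression
and accessibility fold changes are negative ("closing direction") and the
accessibility change is itself significant.

Class-level summaries (TNFi vs the JAK-inhibitor class) require a pair to
be called unanimously across all of a class's treatments to count as
class-called; class-specific and shared sets are derived by set algebra.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["call_drug_targets", "summarize_by_drug_class"]


def _explode_overlap(overlap: pd.DataFrame) -> pd.DataFrame:
    """One row per (locus, condition, element, gene) from the packed table."""
    rows = []
    for r in overlap.itertuples(index=False):
        for el in r.element_ids.split(","):
            for gn in r.gene_ids.split(","):
                rows.append((r.locus_id, r.condition, el, gn))
    return pd.DataFrame(rows, columns=["locus_id", "condition", "element_id", "gene_id"])


def call_drug_targets(
    diff_expr: dict[str, pd.DataFrame],
    diff_acc: dict[str, pd.DataFrame],
    overlap_table: pd.DataFrame,
    abc_pairs_by_condition: dict[str, pd.DataFrame] | None = None,
    expr_q_max: float = 0.05,
    acc_q_max: float = 0.05,
) -> pd.DataFrame:
    """Emit drug-target calls joining expression, accessibility and risk overlap.

    ``diff_expr`` / ``diff_acc`` map treatment -> differential table
    (indexed by feature) for the treatment-vs-NT contrast.  The overlap
    table's condition column must name the treatment it was computed for
    (its ``treatment_timepoint`` condition label is matched on its
    treatment prefix).  When an element lacks an accessibility contrast the
    call is still emitted with accessibility fields absent and consistency
    undetermined (NA), with a log message.
    """
    exploded = _explode_overlap(overlap_table)
    if abc_pairs_by_condition is not None:
        valid: set[tuple[str, str]] = set()
        for pairs in abc_pairs_by_condition.values():
            valid |= set(map(tuple, pairs[["element_id", "gene_id"]].itertuples(index=False)))
        exploded = exploded[
            [
                (e, g) in valid
                for e, g in zip(exploded["element_id"], exploded["gene_id"])
            ]
        ]
    rows = []
    for treatment, de in diff_expr.items():
        da = diff_acc.get(treatment)
        sub = exploded[exploded["condition"].str.startswith(treatment)]
        sig_genes = de[de["qvalue"] <= expr_q_max]
        for r in sub.drop(columns=["condition"]).drop_duplicates().itertuples(index=False):
            if r.gene_id not in sig_genes.index:
                continue
            expr_row = de.loc[r.gene_id]
            if da is not None and r.element_id in da.index:
                acc_row = da.loc[r.element_id]
                acc_fc, acc_q = float(acc_row["log2fc"]), float(acc_row["qvalue"])
                consistent = bool(
                    expr_row["log2fc"] < 0 and acc_fc < 0 and acc_q <= acc_q_max
                )
            else:
                log.info(
                    "no accessibility contrast for %s under %s; consistency undetermined",
                    r.element_id, treatment,
                )
                acc_fc, acc_q, consistent = np.nan, np.nan, pd.NA
            rows.append(
                (
                    treatment, r.element_id, r.gene_id, r.locus_id,
                    float(expr_row["log2fc"]), float(expr_row["qvalue"]),
                    acc_fc, acc_q, consistent,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment", "element_id", "gene_id", "locus_id",
            "expr_log2fc", "expr_q", "acc_log2fc", "acc_q", "direction_consistent",
        ],
    )


def summarize_by_drug_class(
    calls: pd.DataFrame,
    class_map: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, set[tuple[str, str]]]]:
    """Per-class counts and shared/specific (element, gene) pair sets.

    A pair is class-called only if it is called in *all* treatments of the
    class (unanimity rule).  Returns a summary DataFrame and a dict with
    per-class called sets plus ``"shared"`` (called in every class) and
    ``"<class>_specific"`` (called in that class and no other).
    """
    classes: dict[str, set[str]] = {}
    for treatment, cls in class_map.items():
        classes.setdefault(cls, set()).add(treatment)
    pairs_by_treatment = {
        t: set(
            map(tuple, calls.loc[calls["treatment"] == t, ["element_id", "gene_id"]].itertuples(index=False))
        )
        for t in class_map
    }
    class_called: dict[str, set[tuple[str, str]]] = {}
    for cls, members in classes.items():
        sets = [pairs_by_treatment.get(t, set()) for t in members]
        class_called[cls] = set.intersection(*sets) if sets else set()
    shared = set.intersection(*class_called.values()) if class_called else set()
    out_sets: dict[str, set[tuple[str, str]]] = dict(class_called)
    out_sets["shared"] = shared
    rows = []
    for cls in sorted(classes):
        others = set().union(*(class_called[c] for c in classes if c != cls)) if len(classes) > 1 else set()
        specific = class_called[cls] - others
        out_sets[f"{cls}_specific"] = specific
        rows.append((cls, len(class_called[cls]), len(specific), len(shared)))
    summary = pd.DataFrame(rows, columns=["drug_class", "n_called", "n_specific", "n_shared"])
    return summary, out_sets
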