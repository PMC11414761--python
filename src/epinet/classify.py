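"""Directional classification of expression changes in evolved mutants.

Each gene's response in a mutant is placed against the ancestor's own
stress response using three differential-expression contrasts: ancestor
stressed vs unstressed (Anc42 vs Anc37), mutant vs ancestor both stressed
(Mut42 vs Anc42), and mutant stressed vs ancestor unstressed
(Mut42 vs Anc37).  With "significant" meaning q below a threshold
(default 0.001):

* restored   — ancestor contrast significant, mutant-vs-Anc42 significant,
               and the mutant moves opposite to the ancestral stress change;
* reinforced — both significant and the mutant moves the same way;
* novel      — ancestor contrast NOT significant but the mutant differs
               from the ancestor at both temperatures;
* unrestored — ancestor contrast significant but the mutant does not
               differ from the stressed ancestor;
* unclassified — any remaining pattern (the four definitions above are
               not exhaustive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .de import DERecord

CATEGORIES = ("restored", "unrestored", "reinforced", "novel", "unclassified")

__all__ = ["EvolChangeCall", "classify_gene", "classify_mutant",
           "classification_table", "CATEGORIES"]


@dataclass(frozen=True)
class EvolChangeCall:
    gene: str
    mutant_id: str
    category: str
    anc_direction: int  # sign of the Anc42-vs-Anc37 log2fc
    mut_direction: int  # sign of the Mut42-vs-Anc42 log2fc


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_gene(
    anc42_vs_anc37: DERecord,
    mut42_vs_anc42: DERecord,
    mut42_vs_anc37: DERecord,
    mutant_id: str = "",
    q_threshold: float = 0.001,
) -> EvolChangeCall:
    """Classify one gene's expression shift in one mutant."""
    recs = {"anc42_vs_anc37": anc42_vs_anc37, "mut42_vs_anc42": mut42_vs_anc42,
            "mut42_vs_anc37": mut42_vs_anc37}
    for name, rec in recs.items():
        if rec is None:
            raise ValueError(f"missing contrast {name}")
    gene = anc42_vs_anc37.gene
    if not (mut42_vs_anc42.gene == gene == mut42_vs_anc37.gene):
        raise ValueError("the three records must refer to the same gene")

    anc_sig = anc42_vs_anc37.q < q_threshold
    mut_sig = mut42_vs_anc42.q < q_threshold
    mut37_sig = mut42_vs_anc37.q < q_threshold
    anc_dir = _sign(anc42_vs_anc37.log2fc)
    mut_dir = _sign(mut42_vs_anc42.log2fc)

    if anc_sig and mut_sig and (anc_dir == 0 or mut_dir == 0):
        category = "unclassified"  # pathological: significant but zero log2fc
    elif anc_sig and mut_sig and mut_dir == -anc_dir:
        category = "restored"
    elif anc_sig and mut_sig and mut_dir == anc_dir:
        category = "reinforced"
    elif (not anc_sig) and mut_sig and mut37_sig:
        category = "novel"
    elif anc_sig and not mut_sig:
        category = "unrestored"
    else:
        category = "unclassified"
    return EvolChangeCall(gene, mutant_id, category, anc_dir, mut_dir)


def classify_mutant(
    anc_records: Sequence[DERecord],
    mut42_records: Sequence[DERecord],
    mut37_records: Sequence[DERecord],
    mutant_id: str,
    q_threshold: float = 0.001,
) -> list[EvolChangeCall]:
    """Classify every gene present in all three contrasts of one mutant."""
    anc = {r.gene: r for r in anc_records}
    m42 = {r.gene: r for r in mut42_records}
    m37 = {r.gene: r for r in mut37_records}
    calls = []
    for gene in sorted(set(anc) & set(m42) & set(m37)):
        calls.append(classify_gene(anc[gene], m42[gene], m37[gene],
                                   mutant_id, q_threshold))
    return calls


def classification_table(
    calls: Iterable[EvolChangeCall],
    intersect_groups: Mapping[str, Sequence[str]] | None = None,
    category: str = "restored",
) -> tuple[pd.DataFrame, dict]:
    """Per-mutant counts by category, plus shared-gene sets across mutants.

    ``intersect_groups`` maps a label to the mutant ids whose ``category``
    gene sets should be intersected; the report carries the intersection's
    genes, its size, and its share of each member's set.
    """
    calls = list(calls)
    df = pd.DataFrame([vars(c) for c in calls])
    if df.empty:
        raise ValueError("no calls supplied")
    counts = (
        df.pivot_table(index="mutant_id", columns="category", values="gene",
                       aggfunc="count", fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    report: dict = {}
    if intersect_groups:
        per_mutant = {
            m: set(sub.loc[sub["category"] == category, "gene"])
            for m, sub in df.groupby("mutant_id")
        }
        for label, members in intersect_groups.items():
            sets = [per_mutant.get(m, set()) for m in members]
            inter = set.intersection(*sets) if sets else set()
            report[label] = {
                "category": category,
                "mutants": list(members),
                "n_shared": len(inter),
                "genes": sorted(inter),
                "pct_of_each": {
                    m: (100.0 * len(inter) / len(per_mutant[m])
                        if per_mutant.get(m) else math.nan)
                    for m in members
                },
            }
    return counts, report
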