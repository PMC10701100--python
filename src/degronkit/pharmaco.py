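"""Drug-resistance detection from IC50 tables.

A *treatment* is a (drug, degron substrate, cancer type) combination. For
each treatment the cohort's cell lines are split into G1 — lines carrying at
least one mutation mapped (±flank window) to any degron of the substrate —
and G2, the degron-wild-type lines. Resistance is called when the arithmetic
mean IC50 (linear μM scale) of G1 strictly exceeds that of G2.

This is a raw mean comparison by design: no significance test is attached to
the flag, and with a single mutant line the call reduces to comparing that
line against the wild-type mean. An optional rank-sum p-value column can be
added for context, but it never changes the flag. The false-positive
behaviour of the rule under no true effect (≈50% of treatments flagged) is
characterised in the test suite and should be kept in mind when
interpreting scans with small groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import DEFAULT_FLANK
from .io import DrugResponseRow
from .stats import mann_whitney_two_tailed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentCall:
    drug: str
    substrate_protein: str
    cancer_type: str
    g1_cell_lines: tuple[str, ...]
    g2_cell_lines: tuple[str, ...]
    g1_mean_ic50: float
    g2_mean_ic50: float
    fold_change: float
    resistant: bool

    def __post_init__(self) -> None:
        if not self.g1_cell_lines or not self.g2_cell_lines:
            raise ValueError("a treatment call requires both groups non-empty")
        if not (self.g1_mean_ic50 > 0 and self.g2_mean_ic50 > 0):
            raise ValueError("group mean IC50 must be positive")
        if self.resistant != (self.g1_mean_ic50 > self.g2_mean_ic50):
            raise ValueError("resistant flag disagrees with the group means")


def split_cell_lines(
    cell_lines: Sequence[str],
    cell_line_mutations: pd.DataFrame,
    degrons: Iterable,
    substrate: str,
    flank: int = DEFAULT_FLANK,
    protein_length: int | None = None,
) -> tuple[list[str], list[str]]:
    """Partition a cohort into degron-mutant (G1) and wild-type (G2) lines.

    ``cell_line_mutations`` has columns cell_line, protein_id, position. A
    line lands in G1 iff it carries at least one mutation whose position
    falls in the ±``flank`` window of any degron of ``substrate``. Duplicate
    cell-line entries in the cohort are de-duplicated with a warning.
    """
    seen: list[str] = []
    for cl in cell_lines:
        if cl in seen:
            warnings.warn(f"cell line {cl!r} listed more than once; de-duplicated")
        else:
            seen.append(cl)

    windows = []
    for d in degrons:
        if d.protein_id != substrate:
            continue
        hi = d.end + flank
        if protein_length is not None:
            hi = min(protein_length, hi)
        windows.append((max(1, d.start - flank), hi))

    muts = cell_line_mutations
    muts = muts[muts["protein_id"] == substrate]
    mutant_lines = set()
    for row in muts.itertuples(index=False):
        pos = int(row.position)
        if any(lo <= pos <= hi for lo, hi in windows):
            mutant_lines.add(row.cell_line)

    g1 = [cl for cl in seen if cl in mutant_lines]
    g2 = [cl for cl in seen if cl not in mutant_lines]
    return g1, g2


def call_treatment(
    drug: str,
    substrate: str,
    cancer_type: str,
    responses: Iterable[DrugResponseRow],
    g1: Sequence[str],
    g2: Sequence[str],
    min_group: int = 1,
    annotate_rank_p: bool = False,
) -> TreatmentCall | None:
    """Compare group mean IC50 for one treatment; None when skipped.

    Means are arithmetic on the linear μM scale. The treatment is skipped
    (with a logged reason) when either group has fewer than ``min_group``
    lines with response data for this drug. Resistant iff the G1 mean
    strictly exceeds the G2 mean.
    """
    ic50 = {
        r.cell_line: r.ic50_um
        for r in responses
        if r.drug == drug and r.cancer_type == cancer_type
    }
    g1_vals = [ic50[cl] for cl in g1 if cl in ic50]
    g2_vals = [ic50[cl] for cl in g2 if cl in ic50]
    if len(g1_vals) < min_group or len(g2_vals) < min_group:
        logger.info(
            "skipping treatment (%s, %s, %s): group sizes %d/%d below min_group=%d",
            drug, substrate, cancer_type, len(g1_vals), len(g2_vals), min_group,
        )
        return None
    g1_mean = float(np.mean(g1_vals))
    g2_mean = float(np.mean(g2_vals))
    call = TreatmentCall(
        drug=drug,
        substrate_protein=substrate,
        cancer_type=cancer_type,
        g1_cell_lines=tuple(cl for cl in g1 if cl in ic50),
        g2_cell_lines=tuple(cl for cl in g2 if cl in ic50),
        g1_mean_ic50=g1_mean,
        g2_mean_ic50=g2_mean,
        fold_change=g1_mean / g2_mean,
        resistant=g1_mean > g2_mean,
    )
    if annotate_rank_p and len(g1_vals) >= 2 and len(g2_vals) >= 2:
        _, p = mann_whitney_two_tailed(g1_vals, g2_vals)
        object.__setattr__(call, "rank_sum_p", p)  # advisory only; never gates the flag
    return call


def resistance_scan(
    responses: Iterable[DrugResponseRow],
    cell_line_mutations: pd.DataFrame,
    degrons: Iterable,
    drug_targets: Mapping[str, Sequence[str] | str],
    flank: int = DEFAULT_FLANK,
    min_group: int = 1,
    protein_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Run the G1/G2 comparison for every (drug, substrate, cancer type).

    Only drugs with a target mapping onto a degron substrate are analysed;
    unmapped drugs are skipped with a warning. The output is one row per
    emitted call, sorted, and independent of input row order.
    """
    responses = list(responses)
    degrons = list(degrons)
    rows = []
    combos = sorted({(r.drug, r.cancer_type) for r in responses})
    for drug, cancer_type in combos:
        targets = drug_targets.get(drug)
        if targets is None:
            warnings.warn(f"drug {drug!r} has no target mapping; skipped")
            continue
        if isinstance(targets, str):
            targets = [targets]
        cohort = sorted(
            {r.cell_line for r in responses if r.drug == drug and r.cancer_type == cancer_type}
        )
        for substrate in sorted(targets):
            plen = protein_lengths.get(substrate) if protein_lengths else None
            g1, g2 = split_cell_lines(
                cohort, cell_line_mutations, degrons, substrate, flank, plen
            )
            if not g1 or not g2:
                continue
            call = call_treatment(
                drug, substrate, cancer_type, responses, g1, g2, min_group
            )
            if call is None:
                continue
            rows.append(
                {
                    "drug": call.drug,
                    "substrate_protein": call.substrate_protein,
                    "cancer_type": call.cancer_type,
                    "n_g1": len(call.g1_cell_lines),
                    "n_g2": len(call.g2_cell_lines),
                    "g1_mean_ic50": call.g1_mean_ic50,
                    "g2_mean_ic50": call.g2_mean_ic50,
                    "fold_change": call.fold_change,
                    "resistant": call.resistant,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "drug", "substrate_protein", "cancer_type", "n_g1", "n_g2",
            "g1_mean_ic50", "g2_mean_ic50", "fold_change", "resistant",
        ],
    )
    return out.sort_values(
        ["drug", "substrate_protein", "cancer_type"], ignore_index=True
    )
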