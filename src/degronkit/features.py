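"""Feature construction for degron candidates.

Each motif match (or annotated degron) is summarised into a fixed-length
multimodal feature vector combining per-residue structural/evolutionary
tracks averaged over the degron span, a local conservation contrast against
the ±`flank` neighbourhood, PTM counts in the flanked window, and the
distribution of potential ubiquitin-acceptor lysines in the flanks.

This module also draws the length-matched background peptides used to train
the classifier (random non-overlapping placements on the same substrate
proteins), and builds the fixed-length fragments used for positional
amino-acid preference matrices (sequence logos).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, PHOSPHO_ACCEPTORS, UBIQUITIN_ACCEPTOR
from .io import ProteinRecord, PTMSite, TrackSet

logger = logging.getLogger(__name__)

#: Keys every FeatureVector carries, in canonical column order.
FEATURE_REGISTRY = (
    "disorder",
    "accessibility",
    "coil",
    "helix",
    "sheet",
    "rigidity",
    "stabilization",
    "conservation_flank_delta",
    "domain_flag",
    "n_phospho",
    "n_ubiq",
    "flank_lysine_count",
    "flank_lysine_min_dist",
)

#: Track names aggregated by a plain mean over the degron span.
_SPAN_MEAN_TRACKS = (
    "disorder",
    "accessibility",
    "coil",
    "helix",
    "sheet",
    "rigidity",
    "stabilization",
    "domain_flag",
)

DEFAULT_FLANK = 11


@dataclass(frozen=True)
class FeatureVector:
    candidate_ref: tuple[str, int, int, str]  # (protein_id, start, end, motif_name)
    values: dict[str, float]
    imputed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(FEATURE_REGISTRY) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing registry keys {sorted(missing)}")


@dataclass(frozen=True)
class BackgroundPeptide:
    protein_id: str
    start: int
    end: int
    source: str = "background"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _flank_windows(
    start: int, end: int, flank: int, length: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(left, right) flank windows, clipped at the termini; an empty flank is
    returned as an inverted (lo > hi) pair."""
    left = (max(1, start - flank), start - 1)
    right = (end + 1, min(length, end + flank))
    return left, right


def aggregate_features(
    candidate,
    protein: ProteinRecord,
    tracks: TrackSet,
    ptm_sites: Iterable[PTMSite],
    flank: int = DEFAULT_FLANK,
    track_means: Mapping[str, float] | None = None,
) -> FeatureVector:
    """Build the multimodal feature vector for one candidate span.

    Track features are the mean of the per-residue values over the degron
    span [start, end]. ``conservation_flank_delta`` is the span mean minus the
    mean over the two ±``flank`` neighbourhood windows (clipped at termini);
    a positive value means the candidate is more conserved than its
    neighbourhood. PTM counts use the window [start − flank, end + flank]
    clipped to the protein. A track absent for the protein is imputed with
    ``track_means[name]`` (typically the proteome-wide mean) and the vector
    is flagged as imputed for that feature.
    """
    pid, start, end = candidate.protein_id, candidate.start, candidate.end
    motif_name = getattr(candidate, "motif_name", "")
    n = len(protein)
    if not (1 <= start <= end <= n):
        raise ValueError(f"span [{start},{end}] outside protein {pid} (length {n})")
    if flank < 0:
        raise ValueError("flank must be >= 0")

    values: dict[str, float] = {}
    imputed: set[str] = set()
    span = slice(start - 1, end)

    for feat in _SPAN_MEAN_TRACKS:
        track = tracks.get(pid, feat)
        if track is not None:
            values[feat] = float(np.mean(track[span]))
        elif track_means is not None and feat in track_means:
            values[feat] = float(track_means[feat])
            imputed.add(feat)
        else:
            raise KeyError(
                f"protein {pid} lacks track {feat!r} and no imputation mean given"
            )

    cons = tracks.get(pid, "conservation")
    if cons is not None:
        span_mean = float(np.mean(cons[span]))
        flank_vals: list[float] = []
        for lo, hi in _flank_windows(start, end, flank, n):
            if lo <= hi:
                flank_vals.extend(cons[lo - 1 : hi])
        # a degron filling the whole protein has no neighbourhood: delta 0
        values["conservation_flank_delta"] = (
            span_mean - float(np.mean(flank_vals)) if flank_vals else 0.0
        )
    elif track_means is not None and "conservation_flank_delta" in track_means:
        values["conservation_flank_delta"] = float(
            track_means["conservation_flank_delta"]
        )
        imputed.add("conservation_flank_delta")
    else:
        raise KeyError(f"protein {pid} lacks track 'conservation'")

    win_lo, win_hi = max(1, start - flank), min(n, end + flank)
    n_phospho = n_ubiq = 0
    for site in ptm_sites:
        if site.protein_id != pid or not win_lo <= site.position <= win_hi:
            continue
        if site.ptm_type == "phosphorylation":
            n_phospho += 1
        else:
            n_ubiq += 1
    values["n_phospho"] = float(n_phospho)
    values["n_ubiq"] = float(n_ubiq)

    lys_count = 0
    lys_min_dist = 0
    for lo, hi in _flank_windows(start, end, flank, n):
        for pos in range(lo, hi + 1):
            if protein.residue(pos) == UBIQUITIN_ACCEPTOR:
                lys_count += 1
                dist = start - pos if pos < start else pos - end
                if lys_min_dist == 0 or dist < lys_min_dist:
                    lys_min_dist = dist
    values["flank_lysine_count"] = float(lys_count)
    # conventionally 0 when no flank lysine exists; flank_lysine_count
    # doubles as the presence flag
    values["flank_lysine_min_dist"] = float(lys_min_dist)

    return FeatureVector(
        candidate_ref=(pid, start, end, motif_name),
        values=values,
        imputed=frozenset(imputed),
    )


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (one row per candidate, registry order),
    indexed by candidate, with an ``imputed`` indicator column."""
    rows = []
    for v in vectors:
        row = {"candidate_ref": "|".join(map(str, v.candidate_ref))}
        row.update({k: v.values[k] for k in FEATURE_REGISTRY})
        row["imputed"] = bool(v.imputed)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(
    proteome: Mapping[str, ProteinRecord],
    positives: Sequence,
    k_per_positive: int = 10,
    seed: int = 0,
) -> list[BackgroundPeptide]:
    """Length-matched random background peptides on the same substrates.

    For each positive span a set of up to ``k_per_positive`` equally long
    peptides is drawn uniformly (without replacement) from the placements on
    the same protein that overlap no positive span of that protein. When too
    few placements exist, fewer peptides are returned with a warning — an
    overlapping background peptide is never emitted.
    """
    rng = np.random.default_rng(seed)
    spans_by_protein: dict[str, list[tuple[int, int]]] = {}
    for p in positives:
        spans_by_protein.setdefault(p.protein_id, []).append((p.start, p.end))

    out: list[BackgroundPeptide] = []
    for p in positives:
        protein = proteome[p.protein_id]
        length = p.end - p.start + 1
        blocked = spans_by_protein[p.protein_id]
        valid = [
            s
            for s in range(1, len(protein) - length + 2)
            if all(s + length - 1 < lo or s > hi for lo, hi in blocked)
        ]
        if not valid:
            warnings.warn(
                f"no non-overlapping length-{length} placement on "
                f"{p.protein_id}; positive at [{p.start},{p.end}] gets no background"
            )
            continue
        take = min(k_per_positive, len(valid))
        if take < k_per_positive:
            warnings.warn(
                f"only {take}/{k_per_positive} background placements available "
                f"on {p.protein_id} for span [{p.start},{p.end}]"
            )
        starts = rng.choice(len(valid), size=take, replace=False)
        for idx in sorted(starts):
            s = valid[idx]
            out.append(BackgroundPeptide(p.protein_id, s, s + length - 1))
    return out


# ---------------------------------------------------------------------------
# Unified fragments and positional preferences
# ---------------------------------------------------------------------------

def unify_fragments(
    candidates: Sequence,
    proteome: Mapping[str, ProteinRecord],
    length: int = 20,
) -> list[str]:
    """Fixed-length fragments centred on each degron midpoint.

    The midpoint of a span [s, e] is floor((s+e)/2) — even-length spans round
    toward the N-terminus. The fragment covers [c − (length//2 − 1),
    c + length − length//2] and is padded with 'X' beyond the termini, so
    every fragment is exactly ``length`` characters.
    """
    max_len = max((c.end - c.start + 1 for c in candidates), default=0)
    if length < max_len:
        raise ValueError(
            f"fragment length {length} shorter than longest degron ({max_len})"
        )
    fragments = []
    for c in candidates:
        protein = proteome[c.protein_id]
        centre = (c.start + c.end) // 2
        lo = centre - (length // 2 - 1)
        hi = centre + (length - length // 2)
        chars = []
        for pos in range(lo, hi + 1):
            if 1 <= pos <= len(protein):
                chars.append(protein.residue(pos))
            else:
                chars.append("X")
        fragments.append("".join(chars))
    return fragments


@dataclass(frozen=True)
class PositionPreferences:
    """Per-position amino-acid frequencies (rows: positions, cols: AA20).

    Columns where every fragment carried 'X' (pure padding) are undefined:
    their frequency row is all zeros and ``defined`` is False there, rather
    than propagating NaN into downstream consumers.
    """

    frequencies: pd.DataFrame
    defined: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def position_preferences(fragments: Sequence[str]) -> PositionPreferences:
    """Position frequency matrix over the 20 residues, 'X' mass excluded and
    each defined column renormalised to sum to 1."""
    if not fragments:
        raise ValueError("need at least one fragment")
    length = len(fragments[0])
    if any(len(f) != length for f in fragments):
        raise ValueError("fragments have unequal lengths")
    counts = np.zeros((length, len(AA20)))
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    for frag in fragments:
        for i, c in enumerate(frag):
            if c in aa_index:
                counts[i, aa_index[c]] += 1
    totals = counts.sum(axis=1)
    defined = totals > 0
    freqs = np.zeros_like(counts)
    freqs[defined] = counts[defined] / totals[defined, None]
    df = pd.DataFrame(freqs, index=range(1, length + 1), columns=list(AA20))
    return PositionPreferences(frequencies=df, defined=defined)
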