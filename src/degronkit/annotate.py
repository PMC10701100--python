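"""Functional annotation of missense mutations near degrons.

A mutation is mapped onto every degron whose ±``flank``-residue window
(default 11, clipped to the protein) contains its position, then classified
into exactly one of five functional categories describing how it could
perturb degradation signalling:

* ``blocking_phospho`` — removes an annotated phosphorylation site (S/T/Y)
  inside the window, destroying a phospho-degron priming signal;
* ``blocking_ubiq`` — removes an annotated ubiquitination site (K) inside
  the window, deleting a known ubiquitin acceptor;
* ``altering_motif`` — substitutes a residue of the degron itself;
* ``substituting_flanking_lysine`` — replaces a flanking lysine that could
  serve as an ubiquitin acceptor (but is not an annotated site);
* ``rewiring_network`` — any other change in the neighbourhood, with the
  potential to remodel the E3–substrate network.

The first matching rule in a configurable precedence order wins, so the five
categories partition every mapped (mutation, degron) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alphabet import PHOSPHO_ACCEPTORS, UBIQUITIN_ACCEPTOR
from .io import MutationRecord, ProteinRecord, PTMSite

logger = logging.getLogger(__name__)

CATEGORIES = (
    "altering_motif",
    "blocking_phospho",
    "blocking_ubiq",
    "substituting_flanking_lysine",
    "rewiring_network",
)

#: Default rule precedence: the PTM-blocking categories name a specific
#: documented mechanism, so they are tested before the positional rules.
DEFAULT_PRECEDENCE = (
    "blocking_phospho",
    "blocking_ubiq",
    "altering_motif",
    "substituting_flanking_lysine",
    "rewiring_network",
)

DEFAULT_FLANK = 11

REGION_IN_DEGRON = "in_degron"
REGION_IN_FLANK = "in_flank"


@dataclass(frozen=True)
class MutationAnnotation:
    mutation: MutationRecord
    degron_ref: tuple[str, int, int, str]  # (protein_id, start, end, motif_name)
    region: str
    category: str
    mutant_degron_seq: str | None = None  # present iff region == in_degron

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.region not in (REGION_IN_DEGRON, REGION_IN_FLANK):
            raise ValueError(f"unknown region {self.region!r}")


def map_to_degrons(
    mutation: MutationRecord,
    degrons: Iterable,
    flank: int = DEFAULT_FLANK,
    protein_length: int | None = None,
) -> list[tuple[object, str]]:
    """Degrons whose flanked window contains the mutation, with the region.

    The window is [start − flank, end + flank] clipped to [1, protein
    length]; boundaries are inclusive. A mutation can hit several degrons and
    receives one annotation per hit.
    """
    hits = []
    for degron in degrons:
        if degron.protein_id != mutation.protein_id:
            continue
        lo = max(1, degron.start - flank)
        hi = degron.end + flank
        if protein_length is not None:
            hi = min(protein_length, hi)
        if lo <= mutation.position <= hi:
            region = (
                REGION_IN_DEGRON
                if degron.start <= mutation.position <= degron.end
                else REGION_IN_FLANK
            )
            hits.append((degron, region))
    return hits


def _ptm_index(ptm_sites: Iterable[PTMSite]) -> dict[tuple[str, int], set[str]]:
    index: dict[tuple[str, int], set[str]] = {}
    for s in ptm_sites:
        index.setdefault((s.protein_id, s.position), set()).add(s.ptm_type)
    return index


def classify(
    mutation: MutationRecord,
    degron,
    region: str,
    ptm_sites: Iterable[PTMSite] | Mapping[tuple[str, int], set[str]],
    protein: ProteinRecord | None = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> MutationAnnotation:
    """Assign the single functional category for one (mutation, degron) hit.

    Rules are evaluated in ``precedence`` order; ``rewiring_network`` always
    applies, so classification is total. The classification is a pure
    function of its inputs and the precedence configuration.
    """
    if isinstance(ptm_sites, Mapping):
        ptm = ptm_sites
    else:
        ptm = _ptm_index(ptm_sites)
    mods = ptm.get((mutation.protein_id, mutation.position), set())

    def degron_seq() -> str:
        seq = getattr(degron, "matched_seq", None)
        if seq:
            return seq
        if protein is None:
            raise ValueError("need the protein sequence to build the mutant degron")
        return protein.sequence[degron.start - 1 : degron.end]

    rules = {
        "blocking_phospho": lambda: "phosphorylation" in mods
        and mutation.ref_aa in PHOSPHO_ACCEPTORS,
        "blocking_ubiq": lambda: "ubiquitination" in mods
        and mutation.ref_aa == UBIQUITIN_ACCEPTOR,
        "altering_motif": lambda: region == REGION_IN_DEGRON,
        "substituting_flanking_lysine": lambda: region == REGION_IN_FLANK
        and mutation.ref_aa == UBIQUITIN_ACCEPTOR
        and "ubiquitination" not in mods,
        "rewiring_network": lambda: True,
    }
    unknown = set(precedence) - set(rules)
    if unknown:
        raise ValueError(f"unknown categories in precedence: {sorted(unknown)}")

    category = "rewiring_network"
    for name in precedence:
        if rules[name]():
            category = name
            break

    mutant_seq = None
    if region == REGION_IN_DEGRON:
        wt = degron_seq()
        offset = mutation.position - degron.start
        if wt[offset] != mutation.ref_aa:
            raise ValueError(
                f"degron sequence disagrees with mutation reference at "
                f"{mutation.protein_id}:{mutation.position}"
            )
        mutant_seq = wt[:offset] + mutation.alt_aa + wt[offset + 1 :]

    return MutationAnnotation(
        mutation=mutation,
        degron_ref=(
            degron.protein_id,
            degron.start,
            degron.end,
            getattr(degron, "motif_name", ""),
        ),
        region=region,
        category=category,
        mutant_degron_seq=mutant_seq,
    )


def annotate_mutations(
    mutations: Iterable[MutationRecord],
    degrons: Iterable,
    ptm_sites: Iterable[PTMSite],
    proteome: Mapping[str, ProteinRecord] | None = None,
    flank: int = DEFAULT_FLANK,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[MutationAnnotation]:
    """Map every mutation to every degron window it falls in and classify
    each hit; a mutation hitting k degrons yields k annotations."""
    degrons = list(degrons)
    ptm = _ptm_index(ptm_sites)
    out: list[MutationAnnotation] = []
    for mut in mutations:
        protein = proteome.get(mut.protein_id) if proteome else None
        plen = len(protein) if protein else None
        for degron, region in map_to_degrons(mut, degrons, flank, plen):
            out.append(
                classify(mut, degron, region, ptm, protein=protein, precedence=precedence)
            )
    return out


def category_summary(annotations: Iterable[MutationAnnotation]) -> dict[str, int]:
    """Counts per functional category; always reports all five keys, and the
    counts sum to the number of annotations (the categories partition)."""
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    return counts


def annotations_table(annotations: Sequence[MutationAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        m = a.mutation
        rows.append(
            {
                "protein_id": m.protein_id,
                "position": m.position,
                "ref_aa": m.ref_aa,
                "alt_aa": m.alt_aa,
                "sample_id": m.sample_id,
                "source": m.source,
                "degron_start": a.degron_ref[1],
                "degron_end": a.degron_ref[2],
                "motif_name": a.degron_ref[3],
                "region": a.region,
                "category": a.category,
                "mutant_degron_seq": a.mutant_degron_seq or "",
            }
        )
    return pd.DataFrame(rows)
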