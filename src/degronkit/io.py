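"""Readers and writers for the toolkit's external formats.

Sequences travel as FASTA; everything else is tab-separated UTF-8 text with a
header row and ``#`` comment lines. All residue coordinates are 1-based
inclusive, matching protein variant nomenclature (e.g. T368M). Loaders
validate aggressively: malformed structure is an error, while individually
implausible mutation rows (reference mismatch, synonymous, out of bounds) are
dropped with per-reason counts so that no record disappears silently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA20, AA_WITH_X, PHOSPHO_ACCEPTORS, UBIQUITIN_ACCEPTOR

logger = logging.getLogger(__name__)

#: Per-residue annotation features the toolkit understands.
TRACK_REGISTRY = (
    "disorder",
    "accessibility",
    "conservation",
    "coil",
    "helix",
    "sheet",
    "rigidity",
    "stabilization",
    "domain_flag",
)

#: Features whose values must lie in [0, 1].
UNIT_INTERVAL_TRACKS = frozenset(
    {"disorder", "accessibility", "conservation", "coil", "helix", "sheet"}
)

PTM_TYPES = ("phosphorylation", "ubiquitination")


class LoadError(ValueError):
    """Raised when an input file violates its schema or an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise LoadError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - set(AA_WITH_X)
        if bad:
            raise LoadError(
                f"protein {self.protein_id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside protein {self.protein_id} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    sample_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise LoadError(f"mutation position must be >= 1, got {self.position}")
        for aa, label in ((self.ref_aa, "ref_aa"), (self.alt_aa, "alt_aa")):
            if aa not in AA20:
                raise LoadError(f"{label} {aa!r} is not a standard residue")
        if self.ref_aa == self.alt_aa:
            raise LoadError(
                f"synonymous change {self.ref_aa}{self.position}{self.alt_aa}"
            )

    @property
    def short(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


_COMPACT_MUT = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_compact_mutation(text: str) -> tuple[str, int, str]:
    """Expand a compact ``T368M``-style string to (ref, position, alt)."""
    m = _COMPACT_MUT.match(text.strip().upper())
    if m is None:
        raise LoadError(f"cannot parse mutation string {text!r} (expected e.g. T368M)")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class PTMSite:
    protein_id: str
    position: int
    ptm_type: str

    def __post_init__(self) -> None:
        if self.ptm_type not in PTM_TYPES:
            raise LoadError(
                f"unknown PTM type {self.ptm_type!r}; expected one of {PTM_TYPES}"
            )
        if self.position < 1:
            raise LoadError(f"PTM position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class DrugResponseRow:
    cell_line: str
    cancer_type: str
    drug: str
    ic50_um: float

    def __post_init__(self) -> None:
        if not self.ic50_um > 0:
            raise LoadError(
                f"IC50 must be positive, got {self.ic50_um} for "
                f"{self.cell_line}/{self.drug}"
            )


class TrackSet:
    """Per-residue numeric tracks keyed by (protein_id, feature_name)."""

    def __init__(self) -> None:
        self._tracks: dict[tuple[str, str], np.ndarray] = {}

    def set(self, protein_id: str, feature_name: str, values: np.ndarray) -> None:
        if feature_name not in TRACK_REGISTRY:
            raise LoadError(
                f"unknown feature {feature_name!r}; registry: {TRACK_REGISTRY}"
            )
        self._tracks[(protein_id, feature_name)] = np.asarray(values, dtype=float)

    def get(self, protein_id: str, feature_name: str) -> np.ndarray | None:
        return self._tracks.get((protein_id, feature_name))

    def has(self, protein_id: str, feature_name: str) -> bool:
        return (protein_id, feature_name) in self._tracks

    def proteins(self) -> set[str]:
        return {pid for pid, _ in self._tracks}

    def features_for(self, protein_id: str) -> list[str]:
        return [f for (pid, f) in self._tracks if pid == protein_id]

    def feature_mean(self, feature_name: str) -> float:
        """Mean of a feature across every residue of every protein carrying it."""
        chunks = [v for (_, f), v in self._tracks.items() if f == feature_name]
        if not chunks:
            raise KeyError(f"no protein carries track {feature_name!r}")
        return float(np.concatenate(chunks).mean())

    def validate(self, proteome: Mapping[str, ProteinRecord]) -> None:
        for (pid, feat), values in self._tracks.items():
            if pid not in proteome:
                raise LoadError(f"track for unknown protein {pid!r}")
            n = len(proteome[pid])
            if len(values) != n:
                raise LoadError(
                    f"track {feat} for {pid} has {len(values)} values "
                    f"but the protein has {n} residues"
                )
            if feat in UNIT_INTERVAL_TRACKS and (
                np.nanmin(values) < 0 or np.nanmax(values) > 1
            ):
                raise LoadError(f"track {feat} for {pid} leaves [0, 1]")
        # coil+helix+sheet must partition the secondary-structure mass
        for pid in self.proteins():
            ss = [self.get(pid, f) for f in ("coil", "helix", "sheet")]
            if all(v is not None for v in ss):
                total = ss[0] + ss[1] + ss[2]
                if np.max(np.abs(total - 1.0)) > 1e-6:
                    raise LoadError(
                        f"coil+helix+sheet does not sum to 1 for protein {pid}"
                    )

    def __len__(self) -> int:
        return len(self._tracks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrackSet):
            return NotImplemented
        if set(self._tracks) != set(other._tracks):
            return False
        return all(
            np.array_equal(v, other._tracks[k]) for k, v in self._tracks.items()
        )


@dataclass
class DropReport:
    """Accounting of rows dropped during a load, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load a protein FASTA; the header token before the first whitespace is
    the protein id. Sequences are uppercased; duplicate ids are an error."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise LoadError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def as_proteome(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by protein_id, enforcing uniqueness."""
    proteome: dict[str, ProteinRecord] = {}
    for r in records:
        if r.protein_id in proteome:
            raise LoadError(f"duplicate protein id {r.protein_id!r}")
        proteome[r.protein_id] = r
    return proteome


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ("protein_id", "position", "ref_aa", "alt_aa", "sample_id", "source")


def read_mutations(
    path: str | Path, proteome: Mapping[str, ProteinRecord]
) -> tuple[list[MutationRecord], DropReport]:
    """Load a mutation TSV, validating each row against the proteome.

    Rows are dropped (and counted, never silently) when the protein is
    unknown, the position is out of bounds, the stated reference residue does
    not match the sequence, or the change is synonymous.
    """
    df = _read_tsv(path, MUTATION_COLUMNS)
    report = DropReport()
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in proteome:
            report.add("unknown_protein")
            continue
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            report.add("bad_position")
            continue
        protein = proteome[pid]
        if not 1 <= pos <= len(protein):
            report.add("out_of_bounds")
            continue
        ref, alt = str(row.ref_aa).upper(), str(row.alt_aa).upper()
        if ref == alt:
            report.add("synonymous")
            continue
        if protein.residue(pos) != ref:
            report.add("ref_mismatch")
            continue
        try:
            records.append(
                MutationRecord(pid, pos, ref, alt, str(row.sample_id), str(row.source))
            )
        except LoadError:
            report.add("invalid_residue")
    if report.total:
        logger.info("read_mutations dropped %d rows: %s", report.total, report.counts)
    return records, report


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.protein_id, m.position, m.ref_aa, m.alt_aa, m.sample_id, m.source)
            for m in records
        ],
        columns=MUTATION_COLUMNS,
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# PTM sites
# ---------------------------------------------------------------------------

def read_ptm_sites(
    path: str | Path, proteome: Mapping[str, ProteinRecord]
) -> list[PTMSite]:
    """Load PTM sites; residue identity is enforced against the proteome
    (phosphorylation on S/T/Y, ubiquitination on K) and violations are load
    errors, not warnings."""
    df = _read_tsv(path, ("protein_id", "position", "ptm_type"))
    sites: list[PTMSite] = []
    for row in df.itertuples(index=False):
        site = PTMSite(row.protein_id, int(row.position), row.ptm_type)
        if site.protein_id not in proteome:
            raise LoadError(f"PTM site on unknown protein {site.protein_id!r}")
        residue = proteome[site.protein_id].residue(site.position)
        if site.ptm_type == "phosphorylation" and residue not in PHOSPHO_ACCEPTORS:
            raise LoadError(
                f"phosphorylation site at {site.protein_id}:{site.position} "
                f"sits on {residue!r}, expected S/T/Y"
            )
        if site.ptm_type == "ubiquitination" and residue != UBIQUITIN_ACCEPTOR:
            raise LoadError(
                f"ubiquitination site at {site.protein_id}:{site.position} "
                f"sits on {residue!r}, expected K"
            )
        sites.append(site)
    return sites


def write_ptm_sites(sites: Iterable[PTMSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.ptm_type) for s in sites],
        columns=["protein_id", "position", "ptm_type"],
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# Residue tracks (wide TSV: protein_id, position, <feature columns>)
# ---------------------------------------------------------------------------

def read_tracks(
    path: str | Path, proteome: Mapping[str, ProteinRecord]
) -> TrackSet:
    df = _read_tsv(path, ("protein_id", "position"))
    feature_cols = [c for c in df.columns if c not in ("protein_id", "position")]
    unknown = [c for c in feature_cols if c not in TRACK_REGISTRY]
    if unknown:
        raise LoadError(
            f"unknown feature columns {unknown}; registry: {list(TRACK_REGISTRY)}"
        )
    tracks = TrackSet()
    df = df.assign(position=df["position"].astype(int))
    for pid, group in df.groupby("protein_id", sort=False):
        if pid not in proteome:
            raise LoadError(f"tracks for unknown protein {pid!r}")
        n = len(proteome[pid])
        group = group.sort_values("position")
        if list(group["position"]) != list(range(1, n + 1)):
            raise LoadError(
                f"track rows for {pid} do not cover positions 1..{n} exactly"
            )
        for feat in feature_cols:
            values = group[feat].astype(float).to_numpy()
            if np.isnan(values).all():
                continue
            tracks.set(pid, feat, values)
    tracks.validate(proteome)
    return tracks


def write_tracks(
    tracks: TrackSet, proteome: Mapping[str, ProteinRecord], path: str | Path
) -> None:
    frames = []
    for pid in sorted(tracks.proteins()):
        n = len(proteome[pid])
        data: dict[str, object] = {
            "protein_id": [pid] * n,
            "position": list(range(1, n + 1)),
        }
        for feat in TRACK_REGISTRY:
            values = tracks.get(pid, feat)
            if values is not None:
                data[feat] = values
        frames.append(pd.DataFrame(data))
    _write_tsv(pd.concat(frames, ignore_index=True), path)


# ---------------------------------------------------------------------------
# Drug response
# ---------------------------------------------------------------------------

def read_drug_response(path: str | Path) -> list[DrugResponseRow]:
    df = _read_tsv(path, ("cell_line", "cancer_type", "drug", "ic50_um"))
    return [
        DrugResponseRow(
            row.cell_line, row.cancer_type, row.drug, float(row.ic50_um)
        )
        for row in df.itertuples(index=False)
    ]


def write_drug_response(rows: Iterable[DrugResponseRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.cell_line, r.cancer_type, r.drug, r.ic50_um) for r in rows],
        columns=["cell_line", "cancer_type", "drug", "ic50_um"],
    )
    _write_tsv(df, path)
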