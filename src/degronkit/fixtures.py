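"""Synthetic fixtures with ground-truth manifests.

Every downstream module is exercised on fully self-contained synthetic data:
a random proteome with degron motifs implanted at known internal positions,
per-residue feature tracks elevated at the implanted spans by configurable
effect sizes, PTM sites enriched near degrons, mutations engineered so a
known functional category applies, and IC50 tables with engineered
resistance fold-changes. The manifest records every planted truth, so
recovery tests read the manifest rather than re-deriving it.

The generators emulate the *statistical structure* the analysis assumes —
degrons are more disordered, more solvent-accessible and more conserved than
their neighbourhood, PTM signals cluster around them, and resistant
treatments shift the mutant-line IC50 multiplicatively — not the
composition of any real proteome or pharmacology. Background residues are
uniform over the 20 amino acids by default (which keeps chance-match rates
analyzable); a custom residue frequency table can be supplied.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, PHOSPHO_ACCEPTORS, UBIQUITIN_ACCEPTOR
from .annotate import CATEGORIES, DEFAULT_FLANK
from .io import (
    MutationRecord,
    ProteinRecord,
    PTMSite,
    TrackSet,
)
from .motifs import DegronMotif, Token

#: Baseline per-residue track means for the synthetic proteome.
TRACK_BASELINES = {
    "disorder": 0.3,
    "accessibility": 0.3,
    "conservation": 0.4,
    "rigidity": 0.5,
    "stabilization": 0.5,
}

#: Effect sizes mirroring the qualitative contrasts the comparisons assume.
DEFAULT_EFFECT_SIZES = {
    "disorder": 0.4,
    "accessibility": 0.4,
    "conservation": 0.4,
}

DEFAULT_NOISE_SD = 0.1


@dataclass(frozen=True)
class Implant:
    protein_id: str
    start: int
    end: int
    motif_name: str
    sequence: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class FixtureManifest:
    seed: int
    n_proteins: int = 0
    length_range: tuple[int, int] = (0, 0)
    implant_rate: float = 0.0
    implants: list[Implant] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    ptm_rates: dict[str, float] = field(default_factory=dict)
    mutation_labels: list[dict] = field(default_factory=list)
    resistance_treatments: list[dict] = field(default_factory=list)

    def implants_for(self, protein_id: str) -> list[Implant]:
        return [i for i in self.implants if i.protein_id == protein_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_proteins": self.n_proteins,
            "length_range": list(self.length_range),
            "implant_rate": self.implant_rate,
            "implants": [i.__dict__ for i in self.implants],
            "effect_sizes": self.effect_sizes,
            "noise_sd": self.noise_sd,
            "ptm_rates": self.ptm_rates,
            "mutation_labels": self.mutation_labels,
            "resistance_treatments": self.resistance_treatments,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        raw = json.loads(Path(path).read_text())
        m = cls(seed=raw["seed"])
        m.n_proteins = raw["n_proteins"]
        m.length_range = tuple(raw["length_range"])
        m.implant_rate = raw["implant_rate"]
        m.implants = [Implant(**i) for i in raw["implants"]]
        m.effect_sizes = raw["effect_sizes"]
        m.noise_sd = raw["noise_sd"]
        m.ptm_rates = raw["ptm_rates"]
        m.mutation_labels = raw["mutation_labels"]
        m.resistance_treatments = raw["resistance_treatments"]
        return m


def _instantiate_token(token: Token, rng: np.random.Generator) -> str:
    reps = int(rng.integers(token.min_repeat, token.max_repeat + 1))
    allowed = sorted(token.allowed)
    return "".join(allowed[rng.integers(0, len(allowed))] for _ in range(reps))


def instantiate_pattern(motif: DegronMotif, rng: np.random.Generator) -> str:
    """One concrete sequence matching the motif: each class position is drawn
    uniformly from its allowed residues, each repetition bound uniformly."""
    return "".join(_instantiate_token(t, rng) for t in motif.tokens)


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    motif_set: Sequence[DegronMotif],
    implant_rate: float,
    seed: int,
    residue_freqs: Mapping[str, float] | None = None,
    max_retries: int = 50,
) -> tuple[list[ProteinRecord], FixtureManifest]:
    """Random proteome with degrons implanted at known internal coordinates.

    Exactly ``round(implant_rate * n_proteins)`` proteins (chosen at random)
    receive one implant each: a uniformly instantiated motif written over the
    random background at a uniform internal position (never touching residue
    1 or the final residue). Implants never overlap one another by
    construction. The manifest records every implant.
    """
    if not 0.0 <= implant_rate <= 1.0:
        raise ValueError("implant_rate must lie in [0, 1]")
    lo, hi = length_range
    if lo < 5 or hi < lo:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    if residue_freqs is None:
        letters, probs = list(AA20), None
    else:
        letters = sorted(residue_freqs)
        total = sum(residue_freqs.values())
        probs = [residue_freqs[a] / total for a in letters]

    n_implanted = int(round(implant_rate * n_proteins))
    implant_targets = set(
        rng.choice(n_proteins, size=n_implanted, replace=False).tolist()
    )

    proteins: list[ProteinRecord] = []
    manifest = FixtureManifest(seed=seed)
    manifest.n_proteins = n_proteins
    manifest.length_range = (lo, hi)
    manifest.implant_rate = implant_rate
    width = len(str(n_proteins))
    for i in range(n_proteins):
        pid = f"SYN{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        if i in implant_targets:
            for attempt in range(max_retries):
                motif = motif_set[rng.integers(0, len(motif_set))]
                degron_seq = instantiate_pattern(motif, rng)
                # internal placement: start >= 2 and end <= length - 1
                max_start = length - len(degron_seq)
                if max_start < 2:
                    continue
                start = int(rng.integers(2, max_start + 1))
                end = start + len(degron_seq) - 1
                seq = seq[: start - 1] + degron_seq + seq[end:]
                manifest.implants.append(
                    Implant(pid, start, end, motif.motif_name, degron_seq)
                )
                break
            else:
                raise ValueError(
                    f"protein length {length} too short for any motif after "
                    f"{max_retries} retries"
                )
        proteins.append(ProteinRecord(pid, seq))
    return proteins, manifest


def generate_tracks(
    proteome: Sequence[ProteinRecord],
    manifest: FixtureManifest,
    effect_sizes: Mapping[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> TrackSet:
    """Per-residue tracks: clipped-Gaussian baselines, shifted by the
    configured effect size inside implanted spans, clipped to [0, 1] where
    the registry declares a unit range. Secondary-structure tracks are drawn
    jointly and normalised so coil+helix+sheet sums to 1 per residue;
    domain_flag is a Bernoulli(0.2) indicator."""
    if effect_sizes is None:
        effect_sizes = dict(DEFAULT_EFFECT_SIZES)
    unknown = set(effect_sizes) - set(TRACK_BASELINES) - {"coil", "helix", "sheet"}
    if unknown:
        raise KeyError(f"effect sizes for unknown tracks: {sorted(unknown)}")
    rng = np.random.default_rng(manifest.seed + 1 if seed is None else seed)
    manifest.effect_sizes = dict(effect_sizes)
    manifest.noise_sd = noise_sd

    tracks = TrackSet()
    for protein in proteome:
        n = len(protein)
        in_span = np.zeros(n, dtype=bool)
        for imp in manifest.implants_for(protein.protein_id):
            in_span[imp.start - 1 : imp.end] = True
        for feat, baseline in TRACK_BASELINES.items():
            values = rng.normal(baseline, noise_sd, size=n)
            values[in_span] += effect_sizes.get(feat, 0.0)
            tracks.set(protein.protein_id, feat, np.clip(values, 0.0, 1.0))
        ss = np.abs(rng.normal(1.0, 0.3, size=(n, 3))) + 1e-6
        ss /= ss.sum(axis=1, keepdims=True)
        for j, feat in enumerate(("coil", "helix", "sheet")):
            tracks.set(protein.protein_id, feat, ss[:, j])
        tracks.set(
            protein.protein_id,
            "domain_flag",
            (rng.random(n) < 0.2).astype(float),
        )
    return tracks


def generate_ptm_sites(
    proteome: Sequence[ProteinRecord],
    manifest: FixtureManifest,
    rate_near_degron: float = 0.25,
    rate_background: float = 0.01,
    flank: int = DEFAULT_FLANK,
    seed: int | None = None,
) -> list[PTMSite]:
    """PTM sites enriched near implanted degrons.

    Each eligible residue (S/T/Y for phosphorylation, K for ubiquitination)
    becomes an annotated site with probability ``rate_near_degron`` inside
    the ±``flank`` window of an implant and ``rate_background`` elsewhere.
    """
    rng = np.random.default_rng(manifest.seed + 2 if seed is None else seed)
    manifest.ptm_rates = {
        "near_degron": rate_near_degron,
        "background": rate_background,
        "flank": flank,
    }
    sites: list[PTMSite] = []
    for protein in proteome:
        n = len(protein)
        near = np.zeros(n, dtype=bool)
        for imp in manifest.implants_for(protein.protein_id):
            near[max(0, imp.start - 1 - flank) : min(n, imp.end + flank)] = True
        for pos in range(1, n + 1):
            residue = protein.residue(pos)
            rate = rate_near_degron if near[pos - 1] else rate_background
            if residue in PHOSPHO_ACCEPTORS and rng.random() < rate:
                sites.append(PTMSite(protein.protein_id, pos, "phosphorylation"))
            elif residue == UBIQUITIN_ACCEPTOR and rng.random() < rate:
                sites.append(PTMSite(protein.protein_id, pos, "ubiquitination"))
    return sites


class UnachievableCategoryError(ValueError):
    def __init__(self, category: str, requested: int, available: int) -> None:
        super().__init__(
            f"cannot engineer {requested} mutations of category {category!r}; "
            f"only {available} eligible positions exist on the fixture"
        )
        self.category = category


def generate_mutations(
    proteome: Sequence[ProteinRecord],
    manifest: FixtureManifest,
    ptm_sites: Sequence[PTMSite],
    per_category_counts: Mapping[str, int],
    seed: int | None = None,
    flank: int = DEFAULT_FLANK,
    allow_fewer: bool = False,
) -> tuple[list[MutationRecord], list[dict]]:
    """Mutations engineered so the default precedence assigns the intended
    category; returns (records, labels) where each label records the intent.

    A shortfall of eligible positions is an error naming the category, unless
    ``allow_fewer`` is set, in which case every eligible position is used.

    Construction inverts the classification rules: phospho-blocking mutations
    sit on annotated phosphosites in a degron window; ubiquitination-blocking
    ones on annotated K sites; motif-altering ones inside a degron at an
    unannotated position; flanking-lysine substitutions on unannotated flank
    K residues; network-rewiring ones on unannotated non-K flank residues.
    """
    unknown = set(per_category_counts) - set(CATEGORIES)
    if unknown:
        raise KeyError(f"unknown categories requested: {sorted(unknown)}")
    rng = np.random.default_rng(manifest.seed + 3 if seed is None else seed)
    by_protein = {p.protein_id: p for p in proteome}
    annotated: dict[tuple[str, int], set[str]] = {}
    for s in ptm_sites:
        annotated.setdefault((s.protein_id, s.position), set()).add(s.ptm_type)

    pools: dict[str, list[tuple[str, int]]] = {c: [] for c in CATEGORIES}
    for imp in manifest.implants:
        protein = by_protein[imp.protein_id]
        n = len(protein)
        win_lo, win_hi = max(1, imp.start - flank), min(n, imp.end + flank)
        for pos in range(win_lo, win_hi + 1):
            key = (imp.protein_id, pos)
            mods = annotated.get(key, set())
            residue = protein.residue(pos)
            in_degron = imp.start <= pos <= imp.end
            if "phosphorylation" in mods and residue in PHOSPHO_ACCEPTORS:
                pools["blocking_phospho"].append(key)
            elif "ubiquitination" in mods and residue == UBIQUITIN_ACCEPTOR:
                pools["blocking_ubiq"].append(key)
            elif in_degron and residue != "X":
                pools["altering_motif"].append(key)
            elif not in_degron and residue == UBIQUITIN_ACCEPTOR:
                pools["substituting_flanking_lysine"].append(key)
            elif not in_degron and residue != "X":
                pools["rewiring_network"].append(key)

    records: list[MutationRecord] = []
    labels: list[dict] = []
    used: set[tuple[str, int]] = set()
    sample_counter = 0
    for category in CATEGORIES:
        want = int(per_category_counts.get(category, 0))
        if want == 0:
            continue
        pool = sorted(set(pools[category]) - used)
        if len(pool) < want:
            if not allow_fewer:
                raise UnachievableCategoryError(category, want, len(pool))
            want = len(pool)
            if want == 0:
                continue
        picks = rng.choice(len(pool), size=want, replace=False)
        for idx in sorted(picks):
            pid, pos = pool[idx]
            used.add((pid, pos))
            ref = by_protein[pid].residue(pos)
            # the category rules key on ref_aa and the PTM annotation, so any
            # non-synonymous alt preserves the intended label
            alts = [a for a in AA20 if a != ref]
            alt = alts[rng.integers(0, len(alts))]
            sample_counter += 1
            records.append(
                MutationRecord(
                    pid, pos, ref, alt, f"SAMPLE{sample_counter:04d}", "synthetic"
                )
            )
            labels.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "intended_category": category,
                }
            )
    manifest.mutation_labels = labels
    return records, labels


def generate_drug_response(
    manifest: FixtureManifest,
    treatments: Sequence[Mapping],
    n_g1: int = 5,
    n_g2: int = 5,
    baseline_ic50_um: float = 2.0,
    noise_sd_log10: float = 0.2,
    seed: int | None = None,
) -> tuple[list, pd.DataFrame]:
    """IC50 tables with engineered resistance fold-changes.

    Each treatment dict has keys drug, substrate, cancer_type, fold_change
    (> 0). Per treatment, ``n_g1`` designated mutant lines receive one
    mutation inside an implanted degron of the substrate, and their IC50 is
    the lognormal baseline multiplied by the fold change; ``n_g2`` wild-type
    lines carry no substrate mutation. Returns (response rows,
    cell-line-mutation table); intended resistant treatments are recorded in
    the manifest.
    """
    from .io import DrugResponseRow  # local to avoid unused-at-import complaints

    rng = np.random.default_rng(manifest.seed + 4 if seed is None else seed)
    responses: list[DrugResponseRow] = []
    mut_rows: list[dict] = []
    manifest.resistance_treatments = []
    for t_idx, t in enumerate(treatments):
        fold = float(t["fold_change"])
        if fold <= 0:
            raise ValueError(f"fold_change must be positive, got {fold}")
        substrate = t["substrate"]
        implants = manifest.implants_for(substrate)
        if not implants:
            raise ValueError(f"substrate {substrate!r} has no implanted degron")
        degron = implants[0]
        base_mu = np.log10(baseline_ic50_um)
        for j in range(n_g1):
            line = f"CL{t_idx:02d}G1{j:02d}"
            ic50 = 10 ** (base_mu + rng.normal(0.0, noise_sd_log10)) * fold
            responses.append(
                DrugResponseRow(line, t["cancer_type"], t["drug"], float(ic50))
            )
            pos = int(rng.integers(degron.start, degron.end + 1))
            mut_rows.append(
                {"cell_line": line, "protein_id": substrate, "position": pos}
            )
        for j in range(n_g2):
            line = f"CL{t_idx:02d}G2{j:02d}"
            ic50 = 10 ** (base_mu + rng.normal(0.0, noise_sd_log10))
            responses.append(
                DrugResponseRow(line, t["cancer_type"], t["drug"], float(ic50))
            )
        manifest.resistance_treatments.append(
            {
                "drug": t["drug"],
                "substrate": substrate,
                "cancer_type": t["cancer_type"],
                "fold_change": fold,
            }
        )
    mutations = pd.DataFrame(mut_rows, columns=["cell_line", "protein_id", "position"])
    return responses, mutations
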