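import importlib.resources
from pathlib import Path

import pytest

from degronkit import features, fixtures, io, motifs


@pytest.fixture(scope="session")
def example_motifs() -> list[motifs.DegronMotif]:
    path = importlib.resources.files("degronkit").joinpath("data/example_motifs.tsv")
    return motifs.read_motifs(Path(path))


@pytest.fixture(scope="session")
def small_fixture(example_motifs):
    """A modest synthetic data set shared across module tests: 60 proteins,
    half carrying one implanted degron, with tracks, PTM sites, and the
    ground-truth manifest."""
    implantable = [m for m in example_motifs if m.motif_name != "APC_KEN"]
    proteome, manifest = fixtures.generate_proteome(
        n_proteins=60, length_range=(80, 300), motif_set=implantable,
        implant_rate=0.5, seed=11,
    )
    by_id = io.as_proteome(proteome)
    tracks = fixtures.generate_tracks(proteome, manifest)
    ptm = fixtures.generate_ptm_sites(proteome, manifest)
    return {
        "proteome": proteome,
        "by_id": by_id,
        "manifest": manifest,
        "tracks": tracks,
        "ptm": ptm,
    }


@pytest.fixture(scope="session")
def small_feature_tables(small_fixture):
    """Positive (implant) and background feature tables on the small fixture."""
    by_id = small_fixture["by_id"]
    manifest = small_fixture["manifest"]
    tracks, ptm = small_fixture["tracks"], small_fixture["ptm"]
    positives = [
        features.aggregate_features(i, by_id[i.protein_id], tracks, ptm)
        for i in manifest.implants
    ]
    bg_peps = features.sample_background(by_id, manifest.implants, 3, seed=12)
    background = [
        features.aggregate_features(b, by_id[b.protein_id], tracks, ptm)
        for b in bg_peps
    ]
    return features.feature_table(positives), features.feature_table(background)
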