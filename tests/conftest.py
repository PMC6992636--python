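"""Shared phantom fixtures.

The expensive fixtures (full 3 x 3-mm volumes and their segmentation) are
session-scoped: several test modules read them, none mutates them in place.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import plexuscan.density_bscan as dbs
import plexuscan.phantom as ph
import plexuscan.slabs as sl

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@dataclass
class PhantomBundle:
    geometry: ph.ScanGeometry
    surfaces: object          # generator truth surfaces
    truth: ph.PhantomTruth
    volume: object
    annotations: ph.PhantomAnnotations
    measured: object = None   # surfaces segmented from the structural grid


def _make_bundle(truth, geometry, seed):
    surfaces = ph.make_layer_surfaces(geometry)
    volume, annotations = ph.synthesize_volume(truth, surfaces, geometry,
                                               seed=seed)
    measured = sl.segment_surfaces(volume.structural, geometry)
    return PhantomBundle(geometry=geometry, surfaces=surfaces, truth=truth,
                         volume=volume, annotations=annotations,
                         measured=measured)


@pytest.fixture(scope="session")
def default_truth():
    return ph.make_plexus_truth(seed=1)


@pytest.fixture(scope="session")
def foveal_bundle(default_truth):
    """Full-size 3 x 3-mm phantom centred on the fovea (seed 1)."""
    return _make_bundle(default_truth, ph.ScanGeometry(), seed=1)


@pytest.fixture(scope="session")
def small_bundle(default_truth):
    """Cheap 1 x 1-mm phantom centred at 1 mm temporal."""
    geometry = ph.ScanGeometry(extent_x_mm=1.0, extent_y_mm=1.0,
                               n_ascans=100, n_bscans=100,
                               centre_offset_mm=(1.0, 0.0))
    return _make_bundle(default_truth, geometry, seed=1)


@pytest.fixture(scope="session")
def two_plexus_bundle():
    """Peripheral phantom at 10 mm with no ICP and SVP/DCP 55 µm apart."""
    cfg = ph.TruthConfig(
        depth_anchors={"SVP": [(1, 46.0)], "ICP": [(1, 80.0)],
                       "DCP": [(1, 101.0)]},
        density_anchors={s: {**ph.DEFAULT_DENSITY_ANCHORS[s],
                             "ICP": [(1, 0.0)]}
                         for s in ph.SECTORS})
    truth = ph.make_plexus_truth(cfg, seed=2)
    geometry = ph.ScanGeometry(centre_offset_mm=(10.0, 0.0))
    return _make_bundle(truth, geometry, seed=2)


@dataclass
class BandBundle:
    truth: ph.PhantomTruth
    face_sets: list
    nominal_px: list
    layout: object
    band: object
    pitch_mm: float


@pytest.fixture(scope="session")
def small_band(default_truth):
    """Short horizontal band: 8 overlapping 1.5-mm volumes spanning ±3.5 mm."""
    import plexuscan.montage as mtg
    from plexuscan.pipeline import (_band_centres, _snapped_geometry,
                                    _volume_enfaces)

    pitch = 0.01
    face_sets, nominal = [], []
    for c in _band_centres(3.5, 1.5, 0.4):
        geom = _snapped_geometry((c, 0.0), 1.5, 150, 224, 2.0)
        surfaces = ph.make_layer_surfaces(geom)
        volume, _ = ph.synthesize_volume(default_truth, surfaces, geom, seed=1)
        faces, _ = _volume_enfaces(volume, None)
        nominal.append(round((geom.centre_offset_mm[0] - 0.75) / pitch))
        face_sets.append(faces)
    origin = min(nominal)
    layout = mtg.MontageLayout(
        offsets_px=[(p - origin, 0) for p in nominal], axis="horizontal",
        fovea_px=(-origin, 75), volume_shape=(150, 150), pitch_mm=pitch)
    band = mtg.build_band(face_sets, layout)
    return BandBundle(truth=default_truth, face_sets=face_sets,
                      nominal_px=nominal, layout=layout, band=band,
                      pitch_mm=pitch)


def bscan_chain(bundle):
    """Align, mask and projection-remove a bundle's volume (B-scan chain)."""
    aligned = dbs.align_and_reference(bundle.volume, bundle.measured)
    mask = dbs.vessel_mask_volume(aligned.flow)
    aligned.flow = sl.remove_projection(aligned.flow)
    return aligned, mask


@pytest.fixture(scope="session")
def foveal_chain(foveal_bundle):
    return bscan_chain(foveal_bundle)


@pytest.fixture(scope="session")
def two_plexus_chain(two_plexus_bundle):
    return bscan_chain(two_plexus_bundle)
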