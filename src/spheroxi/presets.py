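"""Ready-made demo scenes reproducing the assay's study conditions.

These presets pin the scenarios used throughout the documentation and the
reproduction script: a six-chamber untreated device (three empty references
with lifetime drift, three consuming spheroids), a single-chamber
morphometry scene at 1 um/px, and a viability scene with 200 placeable
cells.
"""

from __future__ import annotations

from .synthetic_data import AcquisitionConfig, KineticsSpec, SceneConfig

__all__ = [
    "untreated_reference_device",
    "morphometry_scene",
    "viability_scene",
]


def untreated_reference_device(
    seed: int = 0,
) -> tuple[SceneConfig, AcquisitionConfig, KineticsSpec]:
    """Six-chamber untreated device at 4 um/px.

    Three empty reference chambers (top row) whose lifetime drifts
    371.3 -> 364.9 ns over the hour, and three spheroid chambers (bottom
    row) following the untreated depletion kinetics (19.2% at sealing,
    13.9% at 25 min, plateau 13.8%).  The chamber oxygen field is uniform
    (core fraction 1.0): the configured kinetics are chamber-mean levels of
    the dye-filled medium, which is what the per-chamber average reports.
    """
    scene = SceneConfig(
        image_shape=(150, 220),
        pixel_size=4.0,
        chamber_centers=[
            (40.0, 40.0),
            (40.0, 110.0),
            (40.0, 180.0),
            (110.0, 40.0),
            (110.0, 110.0),
            (110.0, 180.0),
        ],
        occupancy=["empty", "empty", "empty", "spheroid", "spheroid", "spheroid"],
        spheroid_diameter=115.0,
        spheroid_core_fraction=1.0,
        rng_seed=seed,
    )
    return scene, AcquisitionConfig(), KineticsSpec()


def morphometry_scene(spheroid_diameter_um: float = 114.9) -> SceneConfig:
    """Single chamber at 1 um/px holding a spheroid of the given diameter."""
    return SceneConfig(
        image_shape=(256, 256),
        pixel_size=1.0,
        chamber_centers=[(128.0, 128.0)],
        occupancy=["spheroid"],
        spheroid_diameter=spheroid_diameter_um,
    )


def viability_scene(seed: int = 0) -> SceneConfig:
    """Single chamber at 1 um/px with a large spheroid footprint so a few
    hundred cell spots can be placed disjointly."""
    return SceneConfig(
        image_shape=(256, 256),
        pixel_size=1.0,
        chamber_centers=[(128.0, 128.0)],
        occupancy=["spheroid"],
        spheroid_diameter=160.0,
        rng_seed=seed,
    )
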