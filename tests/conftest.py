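"""Shared fixtures: small deterministic phantoms and the full study scene.

The heavy 4+4-tooth scene and its pipeline run are session-scoped so the
end-to-end checks share one computation.
"""

import numpy as np
import pytest

import pulpseg as ps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_tooth_case():
    """Single noise-free, blur-free tooth: exact 5-level rendering."""
    return ps.generate_tooth(ps.PhantomSpec(noise_sd=0.0, blur_sigma=0.0))


@pytest.fixture(scope="session")
def clean_tooth_case():
    """Single noise-free tooth with partial-volume blur."""
    return ps.generate_tooth(ps.PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def default_tooth_case():
    """Single tooth under the default study conditions (2% noise)."""
    return ps.generate_tooth(ps.PhantomSpec())


@pytest.fixture(scope="session")
def scene_case():
    """The default 4+4-tooth open-bite study scene (0.25 mm voxels, 2% noise)."""
    return ps.default_scene(seed=1)


@pytest.fixture(scope="session")
def scene_report(scene_case):
    """Full pipeline run on the study scene, with reference metrics."""
    refs = [
        (tooth, pulp, spec.tooth_class)
        for tooth, pulp, spec in zip(
            scene_case.tooth_masks, scene_case.pulp_masks, scene_case.specs
        )
    ]
    return ps.segment_case(scene_case.volume, references=refs)


@pytest.fixture(scope="session")
def two_tooth_case():
    """Two mandibular teeth with one true separation plane between them."""
    spec = ps.PhantomSpec(
        tooth_class=ps.ToothClass(ps.ToothKind.INCISOR, ps.ArchLabel.MANDIBULAR, 41),
        crown_radius=2.5,
        seed=7,
    )
    spec2 = ps.PhantomSpec(
        tooth_class=ps.ToothClass(ps.ToothKind.INCISOR, ps.ArchLabel.MANDIBULAR, 42),
        crown_radius=2.5,
        seed=7,
    )
    return ps.generate_arch_scene({ps.ArchLabel.MANDIBULAR: [spec2, spec]}, seed=7)


@pytest.fixture(scope="session")
def small_scene_case():
    """2+2-tooth open-bite scene at coarser voxels (fast pipeline runs)."""

    def tooth(kind, arch, position):
        return ps.PhantomSpec(
            tooth_class=ps.ToothClass(kind, arch, position),
            crown_radius=2.5,
            voxel_size=0.3,
            seed=3,
        )

    specs = {
        ps.ArchLabel.MANDIBULAR: [
            tooth(ps.ToothKind.CANINE, ps.ArchLabel.MANDIBULAR, 43),
            tooth(ps.ToothKind.INCISOR, ps.ArchLabel.MANDIBULAR, 42),
        ],
        ps.ArchLabel.MAXILLARY: [
            tooth(ps.ToothKind.CANINE, ps.ArchLabel.MAXILLARY, 13),
            tooth(ps.ToothKind.INCISOR, ps.ArchLabel.MAXILLARY, 12),
        ],
    }
    return ps.generate_arch_scene(specs, seed=3)


def mask_dice(a, b):
    av = a.values if hasattr(a, "values") else a
    bv = b.values if hasattr(b, "values") else b
    return 2.0 * np.sum(av & bv) / (av.sum() + bv.sum())
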