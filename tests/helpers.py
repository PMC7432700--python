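"""Analytic fixture builders shared across tests.

These construct contour stacks directly from closed-form geometry (circles
of known radius at known z), independent of the scene generator, so they can
serve as oracles for the reconstruction code.
"""

from __future__ import annotations

import numpy as np

from synmorph.sectioning import ContourStack, Section


def circle(r: float, cx: float = 0.0, cy: float = 0.0, n: int = 256) -> np.ndarray:
    a = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(a), cy + r * np.sin(a)])


def sphere_stack(
    radius: float = 500.0,
    thickness: float = 10.0,
    center_xy: tuple[float, float] = (0.0, 0.0),
    margin_sections: int = 2,
) -> ContourStack:
    """Serial sections of a sphere centred at z = 0."""
    z0 = -radius - (margin_sections + 0.5) * thickness
    sections = []
    k = 0
    z = z0
    while z < radius + margin_sections * thickness:
        zm = z + thickness / 2.0
        polys = {}
        if abs(zm) < radius:
            r = np.sqrt(radius**2 - zm**2)
            polys = {"bouton": [circle(r, *center_xy)]}
        sections.append(Section(index=k, z_lo=z, z_hi=z + thickness, polygons=polys))
        z += thickness
        k += 1
    return ContourStack(sections=sections, alignment_state="aligned")


def cylinder_stack(
    radius: float = 400.0,
    height: float = 1100.0,
    thickness: float = 55.0,
    margin_sections: int = 2,
) -> ContourStack:
    """Serial sections of a cylinder spanning z in [0, height].

    Sections are laid out so that contour mid-planes land exactly on z = 0
    and z = height; the lofted model then spans the full analytic height.
    """
    z0 = -thickness / 2.0 - margin_sections * thickness
    sections = []
    k = 0
    z = z0
    while z < height + (margin_sections + 0.5) * thickness:
        zm = z + thickness / 2.0
        polys = {}
        if -1e-9 <= zm <= height + 1e-9:
            polys = {"bouton": [circle(radius)]}
        sections.append(Section(index=k, z_lo=z, z_hi=z + thickness, polygons=polys))
        z += thickness
        k += 1
    return ContourStack(sections=sections, alignment_state="aligned")


def shift_stack(stack: ContourStack, shifts: np.ndarray) -> ContourStack:
    """Apply known per-section in-plane shifts (misalignment injection)."""
    sections = []
    for s, sh in zip(stack.sections, shifts):
        sections.append(
            Section(
                index=s.index,
                z_lo=s.z_lo,
                z_hi=s.z_hi,
                lost=s.lost,
                polygons={k: [p + sh for p in v] for k, v in s.polygons.items()},
                polylines={k: [p + sh for p in v] for k, v in s.polylines.items()},
                marks=list(s.marks),
                shift_true=np.asarray(sh, dtype=float),
            )
        )
    return ContourStack(sections=sections, alignment_state="raw")
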