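"""Eight-contact cylindrical DBS lead geometry.

The modelled lead is a scaled-down human-style array: 2F shaft (0.667 mm
diameter), eight annular contacts of 0.5 mm height separated by 0.25 mm
gaps, giving a 0.75 mm center-to-center pitch.  Contact index 0 is the
distal-most (tip-side) contact and index 7 the proximal-most; this matches
the clinical numbering in which contacts 4-7 are the proximal four.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LeadSpec", "make_lead"]

CONTACT_PITCH_MM = 0.75          # 0.5 mm contact height + 0.25 mm gap
CONTACT_HEIGHT_MM = 0.5
LEAD_RADIUS_MM = 0.667 / 2.0     # 2 French shaft
ENCAPSULATION_THICKNESS_MM = 0.25
ENCAPSULATION_SIGMA = 0.18       # S/m, fibrotic sheath
LEAD_BODY_SIGMA = 1e-6           # S/m, insulating shaft
CONTACT_SIGMA = 1e3              # S/m, metal contact band
DOMAIN_RADIUS_MM = 20.0          # tissue sphere radius


@dataclass
class LeadSpec:
    """Pose and geometry of the implanted lead.

    ``tip`` is the distal tip position (mm); ``direction`` the unit vector
    pointing from tip toward the proximal end (the entry trajectory).  The
    ground return is a patch on the tissue-sphere boundary where the lead
    trajectory exits the domain, standing in for a grounded cranial chamber.
    """

    tip: np.ndarray
    direction: np.ndarray
    domain_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = LEAD_RADIUS_MM
    contact_height: float = CONTACT_HEIGHT_MM
    contact_pitch: float = CONTACT_PITCH_MM
    n_contacts: int = 8
    encapsulation_thickness: float = ENCAPSULATION_THICKNESS_MM
    encapsulation_sigma: float = ENCAPSULATION_SIGMA
    lead_body_sigma: float = LEAD_BODY_SIGMA
    contact_sigma: float = CONTACT_SIGMA
    domain_radius: float = DOMAIN_RADIUS_MM
    ground_patch_radius: float = 5.0

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.domain_center = np.asarray(self.domain_center, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("lead direction must be nonzero")
        self.direction = self.direction / n
        if self.encapsulation_thickness <= 0:
            raise ValueError("encapsulation thickness must be positive")
        r = np.linalg.norm(self.contact_centers() - self.domain_center, axis=1)
        if (r >= self.domain_radius).any():
            raise ValueError("lead contacts exit the tissue domain")

    def contact_centers(self) -> np.ndarray:
        """(8, 3) contact centers, index 0 distal ... 7 proximal."""
        offs = self.contact_height / 2.0 + self.contact_pitch * np.arange(
            self.n_contacts
        )
        return self.tip[None, :] + offs[:, None] * self.direction[None, :]

    def shaft_top(self) -> np.ndarray:
        """Proximal end of the modelled shaft (mm), past the last contact."""
        length = self.contact_height / 2.0 + self.contact_pitch * self.n_contacts
        return self.tip + length * self.direction

    def ground_point(self) -> np.ndarray:
        """Center of the boundary ground patch: domain exit of the trajectory."""
        return self.domain_center + self.domain_radius * self.direction

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from points to the lead shaft segment (tip..top)."""
        p = np.atleast_2d(points) - self.tip
        top = self.shaft_top() - self.tip
        length = np.linalg.norm(top)
        t = np.clip(p @ self.direction, 0.0, length)
        closest = t[:, None] * self.direction[None, :]
        return np.linalg.norm(p - closest, axis=1)

    def shifted(self, shift) -> "LeadSpec":
        """Rigidly translate the lead (used for lead-location sweeps)."""
        return make_lead(
            tip=self.tip + np.asarray(shift, dtype=float),
            direction=self.direction,
            domain_center=self.domain_center,
            domain_radius=self.domain_radius,
        )


def make_lead(
    tip,
    direction,
    shift=(0.0, 0.0, 0.0),
    domain_center=(0.0, 0.0, 0.0),
    domain_radius: float = DOMAIN_RADIUS_MM,
) -> LeadSpec:
    """Build a lead at a pose, optionally rigidly shifted.

    Raises if any contact falls outside the tissue sphere.
    """
    tip = np.asarray(tip, dtype=float) + np.asarray(shift, dtype=float)
    return LeadSpec(
        tip=tip,
        direction=np.asarray(direction, dtype=float),
        domain_center=np.asarray(domain_center, dtype=float),
        domain_radius=domain_radius,
    )
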