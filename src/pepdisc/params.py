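"""Shared analysis parameters.

All lengths are in nm, angles in degrees, energies in kJ/mol and
temperatures in K.  The defaults reproduce the conventions used for
Martini-style coarse-grained nanodisc systems: a 320 K thermostat
temperature, a 0.6 nm salt-bridge contact cutoff, an R13-R13 dimer
window of 0-1 nm, the (1.75 nm, 135 deg) free-energy reference state,
and bead van der Waals radii of 0.264/0.225/0.185 nm for
regular/small/tiny beads with a regular-bead (0.264 nm) probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

#: Molar gas constant in kJ/(mol K).
GAS_CONSTANT = 0.008314


@dataclass(frozen=True)
class AnalysisParameters:
    """Bundle of every tunable cutoff and constant used by the analyses."""

    temperature: float = 320.0
    gas_constant: float = GAS_CONSTANT
    #: (distance nm, angle deg) reference state of the dimer free-energy map.
    fe_reference: tuple[float, float] = (1.75, 135.0)
    charged_contact_cutoff: float = 0.6
    dimer_r13_max: float = 1.0
    parallel_class: tuple[float, float] = (0.0, 60.0)
    antiparallel_class: tuple[float, float] = (120.0, 180.0)
    cluster_cutoffs: tuple[float, ...] = (1.0, 1.25)
    lcat_contact_cutoff: float = 3.0
    siteA_d1_max: float = 1.0
    siteA_d2_max: float = 2.0
    bead_radii: dict[str, float] = field(
        default_factory=lambda: {"regular": 0.264, "small": 0.225, "tiny": 0.185}
    )
    probe_radius: float = 0.264
    density_bin: float = 0.2
    heatmap_cutoff: float = 0.6
    # histogram defaults
    radial_bin: float = 0.1
    angle_bin: float = 2.5
    landscape_r_bin: float = 0.05
    landscape_theta_bin: float = 5.0
    sasa_points: int = 960
    roll_flip_threshold: float = 90.0

    def __post_init__(self) -> None:
        lengths = (
            self.charged_contact_cutoff,
            self.dimer_r13_max,
            self.lcat_contact_cutoff,
            self.siteA_d1_max,
            self.siteA_d2_max,
            self.probe_radius,
            self.density_bin,
            self.heatmap_cutoff,
            self.radial_bin,
            self.landscape_r_bin,
            self.fe_reference[0],
        )
        if any(x <= 0 for x in lengths):
            raise ValueError("all length parameters must be positive")
        if any(r <= 0 for r in self.bead_radii.values()):
            raise ValueError("bead radii must be positive")
        for lo, hi in (self.parallel_class, self.antiparallel_class):
            if not (0.0 <= lo < hi <= 180.0):
                raise ValueError("angle classes must be within [0, 180] degrees")
        if self.antiparallel_class[0] <= self.parallel_class[1]:
            raise ValueError(
                "antiparallel class must start above the parallel class"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def with_overrides(self, **kwargs: Any) -> "AnalysisParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature


DEFAULT_PARAMS = AnalysisParameters()
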