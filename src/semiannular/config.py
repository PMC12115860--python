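"""Run configuration: every tunable threshold of the pipeline in one place.

All thresholds are in normalized gray units (image gray levels live in
``[0, 1]``) or whole pixels; defaults are logged at pipeline start so any
run can be reproduced from its log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and conventions of the full pipeline.

    tau_e
        Background-residual threshold flagging target pixels.
    min_component_px, merge_radius
        Component screening: minimum component size and fragment-joining
        radius for interval detection.
    eps_zero, tau_jump, l_min
        Row classifier: zero-gradient tolerance, edge-jump threshold and
        minimum main-spot zero-run length.
    tau_low
        Refinement: in-annulus pixels dimmer than this are repaired.
    width_tol
        Ring widths deviating more than this (pixels) from the stack
        prediction are corrected.
    spot_threshold
        Gray level above which a cleaned pixel counts as spot during ring
        measurement.
    background_mode
        ``"median"`` or ``"constant:<v>"`` -- background value used by
        refinement.
    orientation_positive
        Which half-annulus orientation encodes positive defocus.
    z_mode
        ``"from_radius"`` (relative z proportional to measured inner
        radius) or ``"equal_spacing"`` (surfaces at z = 1, 2, ...).
    reconstruct_focus
        Add the focused surface's point spot (Airy footprint) when two or
        more defocused rings fix the stack scales.
    focus_footprint_px
        Whole-pixel extent of the reconstructed focus point.
    calibration_um_per_px
        Optional physical scale turning relative z into micrometres; when
        unset all defocus values are relative.
    refine
        Apply annulus beautification to the cleaned rings.
    """

    tau_e: float = 0.08
    min_component_px: int = 20
    merge_radius: int = 2
    eps_zero: float = 0.01
    tau_jump: float = 0.05
    l_min: int = 8
    tau_low: float = 0.1
    width_tol: float = 3.0
    spot_threshold: float = 0.1
    background_mode: str = "median"
    orientation_positive: str = "upper"
    z_mode: str = "from_radius"
    reconstruct_focus: bool = False
    focus_footprint_px: int = 2
    calibration_um_per_px: float | None = None
    refine: bool = True

    def __post_init__(self) -> None:
        if self.z_mode not in ("from_radius", "equal_spacing"):
            raise ValueError("z_mode must be 'from_radius' or 'equal_spacing'")
        if self.orientation_positive not in ("upper", "lower"):
            raise ValueError("orientation_positive must be 'upper' or 'lower'")
        if not (self.background_mode == "median" or self.background_mode.startswith("constant:")):
            raise ValueError("background_mode must be 'median' or 'constant:<value>'")

    def background_value(self) -> float | None:
        """Constant background value, or None for the median mode."""
        if self.background_mode.startswith("constant:"):
            return float(self.background_mode.split(":", 1)[1])
        return None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
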