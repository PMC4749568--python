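"""Simulation configuration for serial-section immunogold experiments.

The model world is a stack of ultrathin serial sections (40 nm by default)
crossed by neurite profiles. Dense-core vesicles (DCVs) occupy neurites in
bursts; immunogold deposition on a labeled section is proportional to local
DCV content, with antibody cross-reactivity, an area-proportional background
and incomplete silver enhancement.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

#: The 11 neuropeptide antibodies of the reference panel.
DEFAULT_ANTIBODY_PANEL: tuple[str, ...] = (
    "FMRFa", "RYa", "MIP", "RGWa", "PENK", "LUQ",
    "ATO", "PDF", "LEUC", "FVa", "FVRIa",
)

#: Whole-body series statistics (HT9-4 specimen).
WHOLE_BODY_N_SECTIONS = 5056
WHOLE_BODY_N_LABELED_SECTIONS = 154

#: VNC series (HT9-5): 200 sections cut from the first trunk segment.
VNC_SERIES_N_SECTIONS = 200

SECTION_THICKNESS_NM = 40.0

#: Dense-core vesicle diameter model (nm): measured on 100 vesicles.
DCV_DIAMETER_MEAN_NM = 63.0
DCV_DIAMETER_SD_NM = 8.4

#: Clear (classical neurotransmitter) vesicle diameter model (nm).
CLEAR_VESICLE_MEAN_NM = 35.0
CLEAR_VESICLE_SD_NM = 5.0


class ConfigurationError(ValueError):
    """A SimConfig field is outside its valid domain."""


@dataclass
class SimConfig:
    """Parameters of the synthetic serial-section immunogold experiment.

    Attributes
    ----------
    n_sections : int
        Number of serial sections in the stack.
    section_thickness_nm : float
        Physical thickness of one section.
    n_neurites : int
        Number of neurite profiles crossing the stack. With
        ``bilateral=True`` this must be even; profiles come in mirrored
        left/right pairs.
    antibody_panel : tuple of str
        Ordered antibody names. The cognate peptide of antibody ``a`` is
        named ``a`` as well.
    crossreactivity : dict
        ``{(antibody, peptide): strength in [0, 1]}``. Missing entries are 0
        except the cognate diagonal, which is always 1.
    dcv_on_rate, dcv_off_rate : float
        Per-section switch probabilities of the two-state DCV occupancy
        chain: P(off -> on) and P(on -> off).
    dcv_mean : float
        Mean DCV count per section while the chain is in the 'on' state.
    gold_per_dcv : float
        Expected raw gold particles deposited per DCV per labeled section
        (before silver-enhancement thinning).
    background_rate : float
        Expected background gold per um^2 of profile area per labeled
        section.
    enhancement_prob : float
        Probability a deposited particle is silver-enhanced and therefore
        countable.
    vesicle_diam_mean_nm, vesicle_diam_sd_nm : float
        DCV diameter model (positive-truncated normal).
    clear_diam_mean_nm, clear_diam_sd_nm : float
        Clear-vesicle diameter model at classical presynapses.
    peptidergic_fraction : float
        Fraction of neurites that are peptidergic (carry >= 1 peptide).
    coexpression_prob : float
        Probability a peptidergic neurite carries a second peptide.
    bilateral : bool
        Generate neurites as mirrored left/right pairs about the x=0
        midline.
    position_jitter_um : float
        Per-section random-walk jitter of neurite centroids.
    seed : int
        Root random seed.
    """

    n_sections: int = VNC_SERIES_N_SECTIONS
    section_thickness_nm: float = SECTION_THICKNESS_NM
    n_neurites: int = 200
    antibody_panel: tuple[str, ...] = DEFAULT_ANTIBODY_PANEL
    crossreactivity: dict = field(default_factory=dict)
    dcv_on_rate: float = 0.2
    dcv_off_rate: float = 0.1
    dcv_mean: float = 4.0
    gold_per_dcv: float = 1.0
    background_rate: float = 0.02
    enhancement_prob: float = 0.5
    vesicle_diam_mean_nm: float = DCV_DIAMETER_MEAN_NM
    vesicle_diam_sd_nm: float = DCV_DIAMETER_SD_NM
    clear_diam_mean_nm: float = CLEAR_VESICLE_MEAN_NM
    clear_diam_sd_nm: float = CLEAR_VESICLE_SD_NM
    peptidergic_fraction: float = 0.25
    coexpression_prob: float = 0.1
    bilateral: bool = True
    position_jitter_um: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.antibody_panel = tuple(self.antibody_panel)
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ConfigurationError("n_sections must be >= 1")
        if self.n_neurites < 0:
            raise ConfigurationError("n_neurites must be >= 0")
        if self.bilateral and self.n_neurites % 2:
            raise ConfigurationError(
                "n_neurites must be even for a bilateral layout"
            )
        if self.section_thickness_nm <= 0:
            raise ConfigurationError("section_thickness_nm must be > 0")
        for name in ("dcv_on_rate", "dcv_off_rate", "enhancement_prob",
                     "peptidergic_fraction", "coexpression_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("dcv_mean", "gold_per_dcv", "background_rate",
                     "vesicle_diam_sd_nm", "clear_diam_sd_nm",
                     "position_jitter_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("vesicle_diam_mean_nm", "clear_diam_mean_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if len(set(self.antibody_panel)) != len(self.antibody_panel):
            raise ConfigurationError("antibody_panel names must be unique")
        for (a, p), s in self.crossreactivity.items():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(
                    f"crossreactivity[{a!r},{p!r}] must be in [0, 1]"
                )
            if a == p and s != 1.0:
                raise ConfigurationError(
                    f"crossreactivity diagonal for {a!r} must be 1"
                )

    # -- derived quantities ----------------------------------------------

    def recognition(self, antibody: str, peptide: str) -> float:
        """Recognition strength S[a, p]; cognate diagonal is always 1."""
        if antibody == peptide:
            return 1.0
        return float(self.crossreactivity.get((antibody, peptide), 0.0))

    @property
    def dcv_stationary_on_fraction(self) -> float:
        """Stationary P(on) of the two-state occupancy chain."""
        q = self.dcv_on_rate + self.dcv_off_rate
        if q == 0.0:
            return 0.0
        return self.dcv_on_rate / q

    def rng(self, *stream: object) -> np.random.Generator:
        """Child generator for a named component stream.

        Per-component streams keep draws independent: adding neurites does
        not perturb existing ones.
        """
        ss = np.random.SeedSequence(
            self.seed,
            spawn_key=tuple(
                zlib.crc32(repr(s).encode("utf-8")) for s in stream
            ),
        )
        return np.random.default_rng(ss)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["antibody_panel"] = list(self.antibody_panel)
        d["crossreactivity"] = [
            [a, p, s] for (a, p), s in sorted(self.crossreactivity.items())
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "crossreactivity" in d and isinstance(d["crossreactivity"], list):
            d["crossreactivity"] = {
                (a, p): float(s) for a, p, s in d["crossreactivity"]
            }
        return cls(**d)


def labeled_section_fraction_percent(
    n_labeled: int = WHOLE_BODY_N_LABELED_SECTIONS,
    n_sections: int = WHOLE_BODY_N_SECTIONS,
) -> float:
    """Labeled-section fraction of a series, in percent.

    With the whole-body defaults (154 of 5056) this rounds to 3%.
    """
    if n_sections < 1 or not 0 <= n_labeled <= n_sections:
        raise ConfigurationError("need 0 <= n_labeled <= n_sections, n >= 1")
    return 100.0 * n_labeled / n_sections
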