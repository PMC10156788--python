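"""Three-cube (sensitized-emission) FRET analysis.

Intensities S_CUBE(SPECIMEN) are measured through three filter cubes
(CFP, YFP, FRET) on cells expressing the donor only (D), the acceptor
only (A), or both (DA).  Single-fluorophore cells give the bleed-through
constants

    R_D1 = S_FRET(D)/S_CFP(D),  R_D2 = S_YFP(D)/S_CFP(D),
    R_A1 = S_FRET(A)/S_YFP(A)

and the FRET ratio of a double-labelled cell is

    FR = [S_FRET(DA) - R_D1*S_CFP(DA)]
         / (R_A1*[S_YFP(DA) - R_D2*S_CFP(DA)])

i.e. the fractional increase of acceptor emission caused by energy
transfer.  The effective efficiency E_EFF = E*A_b = (FR - 1) * eps,
where eps is the acceptor/donor extinction-coefficient ratio at the
FRET-cube excitation wavelength (0.079 for the ECFP/EYFP pair used
here), E the intrinsic efficiency of a bound pair and A_b the bound
fraction of acceptor-tagged molecules (1:1 stoichiometry assumed; the
acceptor must tag the limiting moiety).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CUBES",
    "SPECIMENS",
    "DEFAULT_EXTINCTION_RATIO",
    "ThreeCubeSet",
    "BleedConstants",
    "FretResult",
    "bleed_constants",
    "fret_ratio",
    "effective_efficiency",
    "intensity_gate",
    "fret_distance",
    "analyze_cells",
]

CUBES = ("CFP", "YFP", "FRET")
SPECIMENS = ("D", "A", "DA")

#: epsilon_YFP(440)/epsilon_CFP(440) for the ECFP/EYFP pair through a
#: 440-nm-band FRET-cube excitation filter.
DEFAULT_EXTINCTION_RATIO = 0.079


@dataclass
class ThreeCubeSet:
    """Background-corrected intensities S[cube][specimen].

    Any subset of the 3x3 grid may be present; each computation states
    which entries it needs.  An optional per-cube background is
    subtracted on construction when supplied.
    """

    S: dict
    background: dict | None = None

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, float]] = {}
        for cube, spec_map in self.S.items():
            if cube not in CUBES:
                raise ValueError(f"unknown cube {cube!r}")
            clean[cube] = {}
            for spec, val in spec_map.items():
                if spec not in SPECIMENS:
                    raise ValueError(f"unknown specimen {spec!r}")
                v = float(val)
                if self.background:
                    v -= self.background.get(cube, 0.0)
                if v < 0:
                    raise ValueError(
                        f"negative intensity S_{cube}({spec}) = {v}")
                clean[cube][spec] = v
        self.S = clean

    def get(self, cube: str, specimen: str) -> float:
        try:
            return self.S[cube][specimen]
        except KeyError:
            raise KeyError(f"S_{cube}({specimen}) missing from the set")


@dataclass(frozen=True)
class BleedConstants:
    R_D1: float
    R_D2: float
    R_A1: float
    dispersion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("R_D1", "R_D2", "R_A1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FretResult:
    FR: float
    E_EFF: float
    extinction_ratio: float
    E: float | None = None
    A_b: float | None = None
    distance_A: float | None = None
    R0_A: float | None = None


def bleed_constants(donor_only, acceptor_only) -> BleedConstants:
    """Bleed-through constants from single-fluorophore specimens.

    ``donor_only``/``acceptor_only`` are ThreeCubeSets (or lists of
    them, one per cell; per-cell ratios are averaged and the standard
    deviation reported as dispersion).
    """
    d_sets = donor_only if isinstance(donor_only, (list, tuple)) else [donor_only]
    a_sets = acceptor_only if isinstance(acceptor_only, (list, tuple)) else [acceptor_only]
    rd1, rd2, ra1 = [], [], []
    for s in d_sets:
        denom = s.get("CFP", "D")
        if denom == 0:
            raise ZeroDivisionError("S_CFP(D) is zero in a donor-only cell")
        rd1.append(s.get("FRET", "D") / denom)
        rd2.append(s.get("YFP", "D") / denom)
    for s in a_sets:
        denom = s.get("YFP", "A")
        if denom == 0:
            raise ZeroDivisionError("S_YFP(A) is zero in an acceptor-only cell")
        ra1.append(s.get("FRET", "A") / denom)
    disp = {}
    if len(rd1) > 1:
        disp["R_D1_sd"] = float(np.std(rd1, ddof=1))
        disp["R_D2_sd"] = float(np.std(rd2, ddof=1))
    if len(ra1) > 1:
        disp["R_A1_sd"] = float(np.std(ra1, ddof=1))
    return BleedConstants(R_D1=float(np.mean(rd1)), R_D2=float(np.mean(rd2)),
                          R_A1=float(np.mean(ra1)), dispersion=disp)


def fret_ratio(da: ThreeCubeSet, k: BleedConstants) -> float:
    """FR from a double-labelled specimen after bleed-through removal."""
    s_fret = da.get("FRET", "DA")
    s_cfp = da.get("CFP", "DA")
    s_yfp = da.get("YFP", "DA")
    denom = k.R_A1 * (s_yfp - k.R_D2 * s_cfp)
    if denom <= 0:
        raise ValueError(
            "direct acceptor signal is non-positive after bleed correction; "
            "cell lacks measurable acceptor")
    return (s_fret - k.R_D1 * s_cfp) / denom


def effective_efficiency(FR: float,
                         extinction_ratio: float = DEFAULT_EXTINCTION_RATIO
                         ) -> float:
    """E_EFF = E*A_b = (FR - 1) * extinction ratio."""
    if extinction_ratio <= 0:
        raise ValueError("extinction ratio must be positive")
    e_eff = (FR - 1.0) * extinction_ratio
    if e_eff < 0:
        warnings.warn("FR < 1: negative apparent efficiency")
    return e_eff


def intensity_gate(I_CFP: float, I_YFP: float,
                   bounds: tuple[float, float] = (0.5, 2.0)) -> bool:
    """Accept a cell only if 0.5 < I_CFP/I_YFP < 2.0 (strict bounds).

    Cells with strongly imbalanced fluorophore expression violate the
    assumptions behind the bound-fraction interpretation of E_EFF.
    """
    if I_CFP <= 0 or I_YFP <= 0:
        raise ValueError("intensities must be positive")
    r = I_CFP / I_YFP
    return bounds[0] < r < bounds[1]


def fret_distance(E: float, R0: float) -> float:
    """Donor-acceptor distance r = R0 * (1/E - 1)^(1/6), in Angstrom.

    Requires the intrinsic (not effective) efficiency and a
    user-supplied Foerster radius for the fluorophore pair.
    """
    if not (0.0 < E <= 1.0):
        raise ValueError("intrinsic efficiency must lie in (0, 1]")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def analyze_cells(df: pd.DataFrame, k: BleedConstants,
                  extinction_ratio: float = DEFAULT_EXTINCTION_RATIO,
                  gate: bool = True) -> pd.DataFrame:
    """Per-cell FR and E_EFF from a long-format intensity table.

    ``df`` columns: cell_id, cube, specimen, intensity.  Cells failing
    the CFP/YFP intensity gate are flagged (and excluded from use when
    ``gate``); the cohort summary (mean, s.e.m., n) is attached as
    ``DataFrame.attrs['summary']``.
    """
    required = {"cell_id", "cube", "specimen", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"intensity table needs columns {sorted(required)}")
    rows = []
    for cell, sub in df.groupby("cell_id"):
        S: dict[str, dict[str, float]] = {}
        for _, r in sub.iterrows():
            S.setdefault(r["cube"], {})[r["specimen"]] = r["intensity"]
        tcs = ThreeCubeSet(S)
        fr = fret_ratio(tcs, k)
        accepted = True
        if gate:
            accepted = intensity_gate(tcs.get("CFP", "DA"),
                                      tcs.get("YFP", "DA"))
        rows.append({"cell_id": cell, "FR": fr,
                     "E_EFF": effective_efficiency(fr, extinction_ratio),
                     "accepted": accepted})
    out = pd.DataFrame(rows)
    used = out[out["accepted"]] if gate else out
    n = len(used)
    out.attrs["summary"] = {
        "n": n,
        "FR_mean": float(used["FR"].mean()) if n else np.nan,
        "E_EFF_mean": float(used["E_EFF"].mean()) if n else np.nan,
        "E_EFF_sem": float(used["E_EFF"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
    }
    return out
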