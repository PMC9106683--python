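"""Two-pool delta-13C mixing: attributing bulk isotopic shifts to lignin.

Lignin-derived carbon is isotopically lighter than bulk plant tissue (a
depletion of ~4.3 permil), and the CuO-oxidation VSC method (sum of
vanillyl, syringyl and cinnamyl phenols) recovers only a fraction (~38%) of
total lignin carbon.  Treating SOC as a two-pool mixture of lignin C and a
non-lignin residue with fixed delta-13C, a change in the lignin fraction f
shifts the bulk signature by

    d(delta13C_bulk) = (f_final - f_initial) * (-depletion)

so a relative accumulation of lignin depletes (lowers) bulk delta-13C.  The
fraction of an observed bulk shift explained by lignin accumulation follows
by division.  Kinetic fractionation of the residual pool during advanced
decomposition is outside this model and must be assessed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError

__all__ = [
    "MixingParams",
    "LigninState",
    "vsc_sum",
    "cinnamyl_sum",
    "lignin_fraction",
    "lignin_delta_shift",
    "fraction_of_observed_shift",
]


@dataclass(frozen=True)
class MixingParams:
    """Parameters of the lignin/delta-13C mixing model.

    depletion:
        How much lighter lignin delta-13C is than bulk plant material, in
        permil (default 4.3).
    recovery:
        Fraction of lignin carbon recovered as VSC phenols by the CuO
        method (default 0.38); dividing a VSC fraction by this value
        corrects it to a total-lignin-C fraction.
    """

    depletion: float = 4.3
    recovery: float = 0.38

    def __post_init__(self) -> None:
        if self.depletion < 0:
            raise DataError(f"depletion must be >= 0, got {self.depletion}")
        if not 0 < self.recovery <= 1:
            raise DataError(f"recovery must be in (0, 1], got {self.recovery}")


@dataclass
class LigninState:
    """Lignin status of one sample: VSC fraction of SOC, optional bulk d13C."""

    vsc_fraction: float
    bulk_delta13c: float | None = None

    def __post_init__(self) -> None:
        if self.vsc_fraction < 0:
            raise DataError(f"vsc_fraction must be >= 0, got {self.vsc_fraction}")


def vsc_sum(vanillyl: float, syringyl: float, cinnamyl: float) -> float:
    """Total lignin phenols VSC = V + S + C (any consistent mass units)."""
    if vanillyl < 0 or syringyl < 0 or cinnamyl < 0:
        raise DataError("vsc_sum: negative phenol amount")
    return vanillyl + syringyl + cinnamyl


def cinnamyl_sum(p_coumaric: float, ferulic: float) -> float:
    """Cinnamyl units: sum of p-coumaric and ferulic acid."""
    if p_coumaric < 0 or ferulic < 0:
        raise DataError("cinnamyl_sum: negative acid amount")
    return p_coumaric + ferulic


def lignin_fraction(vsc_fraction: float, params: MixingParams | None = None) -> float:
    """Correct a VSC fraction of SOC to a total lignin-C fraction.

    Divides by the VSC recovery (default 0.38).  A corrected fraction above
    1 is physically impossible and raises.
    """
    params = params or MixingParams()
    if vsc_fraction < 0:
        raise DataError(f"vsc_fraction must be >= 0, got {vsc_fraction}")
    f = vsc_fraction / params.recovery
    if f > 1:
        raise DataError(
            f"recovery inconsistency: VSC {vsc_fraction} / recovery "
            f"{params.recovery} gives lignin fraction {f} > 1"
        )
    return f


def lignin_delta_shift(
    state_initial: LigninState,
    state_final: LigninState,
    params: MixingParams | None = None,
    correct_recovery: bool = True,
) -> float:
    """Bulk delta-13C shift (permil) attributable to the lignin pool change.

    With ``correct_recovery`` (default) VSC fractions are first divided by
    the recovery factor; disabling it treats the inputs as lignin-C
    fractions directly.  Negative output means bulk depletion (lignin
    accumulated); the non-lignin end-member is assumed unchanged.
    """
    params = params or MixingParams()
    if correct_recovery:
        f0 = lignin_fraction(state_initial.vsc_fraction, params)
        f1 = lignin_fraction(state_final.vsc_fraction, params)
    else:
        f0 = state_initial.vsc_fraction
        f1 = state_final.vsc_fraction
    return (f1 - f0) * (-params.depletion)


def fraction_of_observed_shift(lignin_shift: float, observed_shift: float) -> float:
    """Percent of an observed bulk delta-13C shift explained by lignin.

    Both shifts are signed; the result is positive when they point the same
    way and negative (lignin working against the observation) otherwise.
    """
    if observed_shift == 0:
        raise DataError("fraction_of_observed_shift: observed shift is 0")
    return 100.0 * lignin_shift / observed_shift
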