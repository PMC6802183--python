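"""Kinetic rate laws for the hypoxia / tumor-signaling model.

This module collects the small algebraic pieces that make the integrated
model oxygen- and drug-sensitive:

* an algebraic ATP–O₂ relation (Michaelis–Menten in the O₂ fraction),
* ordered bi-substrate (ATP-first) phosphorylation kinetics, with the
  substrate constant ``K^AB`` calibrated so that the ATP-explicit law
  collapses onto the original ATP-implicit Michaelis–Menten law at
  normoxic ATP,
* VEGF synthesis driven by the relative mRNA level raised to a power,
* reversible VEGF–VEGFR binding with competitive inhibition of the
  forward step.

All functions are pure and individually testable; the network layer only
composes them.  Concentrations are nM internally; ATP is carried in μM
(literature convention) and converted at the boundary.

Drug strength is always expressed as the dimensionless ratio ``[D]/K_i``
(``d_over_ki``); an inhibition constant never appears on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ATPModel",
    "PhosphoLaw",
    "VEGFSynthesisLaw",
    "VEGFBindingLaw",
    "atp_level",
    "calibrate_kab",
    "phospho_rate",
    "phospho_rate_inhibited",
    "vegf_synthesis_rate",
    "vegf_binding_rate",
    "UM_TO_NM",
]

#: unit conversion: ATP bookkeeping is in μM, species concentrations in nM.
UM_TO_NM = 1000.0


@dataclass(frozen=True)
class ATPModel:
    """Algebraic map from O₂ (fraction of normoxia) to cellular ATP.

    Parameters
    ----------
    atp_normoxia:
        Maximal (normoxic) ATP concentration in μM.  Default 3000 μM.
    half_max_o2_fraction:
        O₂ fraction (of normoxia) at which ATP is half-maximal.
        Default 0.033, i.e. 3.3% of the normoxic O₂ level.
    """

    atp_normoxia: float = 3000.0
    half_max_o2_fraction: float = 0.033

    def __post_init__(self) -> None:
        if self.atp_normoxia <= 0 or self.half_max_o2_fraction <= 0:
            raise ValueError("ATPModel parameters must be positive")


def atp_level(o2_fraction: float, m: ATPModel = ATPModel()) -> float:
    """ATP concentration (μM) at a given O₂ fraction of normoxia.

    ``[ATP] = ATP_max · f / (f_half + f)`` — hyperbolic in the O₂
    fraction, so ATP stays near-maximal under mild hypoxia and collapses
    only once O₂ drops near ``f_half``.

    Raises
    ------
    ValueError
        If ``o2_fraction`` is not strictly positive.
    """
    if o2_fraction <= 0:
        raise ValueError(f"o2_fraction must be > 0, got {o2_fraction}")
    return m.atp_normoxia * o2_fraction / (m.half_max_o2_fraction + o2_fraction)


def calibrate_kab(k_prime: float, k_m_atp: float, atp_normoxia: float) -> float:
    """Substrate constant ``K^AB`` that preserves the original kinetics at normoxia.

    Solves ``(K_M,ATP / ATP_normoxia + 1) · K^AB = K'`` for ``K^AB`` so that
    the ATP-explicit phosphorylation law evaluated at normoxic ATP equals
    the original ATP-implicit law for every substrate concentration.

    All three arguments must be in the *same* concentration unit.
    """
    if k_prime <= 0 or k_m_atp <= 0 or atp_normoxia <= 0:
        raise ValueError("calibrate_kab requires strictly positive inputs")
    return k_prime / (k_m_atp / atp_normoxia + 1.0)


@dataclass(frozen=True)
class PhosphoLaw:
    """Ordered bi-substrate (ATP binds first) phosphorylation kinetics.

    ``vmax`` is the maximal rate (nM·s⁻¹); ``k_m_atp`` the ATP dissociation
    constant and ``k_ab`` the calibrated substrate constant, both in nM.
    ``k_prime`` retains the original (ATP-implicit) Michaelis constant the
    calibration started from, for provenance.  ``inhibitor_target`` names
    the drug target acting on this reaction, if any.
    """

    vmax: float
    k_m_atp: float = 100.0
    k_ab: float = field(default=0.0)
    k_prime: Optional[float] = None
    inhibitor_target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.k_m_atp <= 0:
            raise ValueError("vmax and k_m_atp must be positive")
        if self.k_ab <= 0:
            raise ValueError("k_ab must be positive (run calibrate_kab first)")
        if self.k_prime is not None and self.k_prime <= 0:
            raise ValueError("k_prime, when given, must be positive")


def phospho_rate(atp: float, protein: float, law: PhosphoLaw) -> float:
    """ATP-dependent phosphorylation rate.

    ``rate = Vmax·[ATP]·[P] / (K_M,ATP·K^AB + K^AB·[ATP] + [ATP]·[P])``,
    equivalently ``Vmax·[P] / ((K_M,ATP/[ATP] + 1)·K^AB + [P])``.

    ``atp`` must be in the same unit as ``law.k_m_atp``; ``protein`` in the
    same unit as ``law.k_ab``.  Monotone increasing in both substrates and
    bounded by ``vmax``.
    """
    if atp <= 0:
        raise ValueError(f"atp must be > 0, got {atp}")
    if protein < 0:
        raise ValueError(f"protein must be >= 0, got {protein}")
    return law.vmax * protein / ((law.k_m_atp / atp + 1.0) * law.k_ab + protein)


def phospho_rate_inhibited(
    atp: float, protein: float, d_over_ki: float, law: PhosphoLaw
) -> float:
    """Phosphorylation rate under an ATP-competitive inhibitor.

    ``rate = Vmax·[ATP]·[P] /
    (K_M,ATP·K^AB·(1+[D]/K_i) + K^AB·[ATP] + [ATP]·[P])``.

    At ``d_over_ki = 0`` this is bit-identical to :func:`phospho_rate`.
    Because the inhibitor multiplies only the ``K_M,ATP·K^AB`` term, the
    rate does **not** vanish at saturating drug: as ``d_over_ki → ∞`` in a
    regime where the other denominator terms stay finite, the rate tends
    to 0 only when ``K_M,ATP·K^AB·[D]/K_i`` dominates; otherwise it
    approaches the drug-insensitive floor
    ``Vmax·[ATP]·[P] / (K^AB·[ATP] + [ATP]·[P]) = Vmax·[P]/(K^AB+[P])``
    — competitive inhibition is surmountable by ATP.  Note the floor is
    only reached asymptotically; for any finite dose the rate is strictly
    decreasing in ``d_over_ki``.
    """
    if d_over_ki < 0:
        raise ValueError(f"d_over_ki must be >= 0, got {d_over_ki}")
    if d_over_ki == 0:
        return phospho_rate(atp, protein, law)
    if atp <= 0:
        raise ValueError(f"atp must be > 0, got {atp}")
    if protein < 0:
        raise ValueError(f"protein must be >= 0, got {protein}")
    denom = (
        law.k_m_atp * law.k_ab * (1.0 + d_over_ki)
        + law.k_ab * atp
        + atp * protein
    )
    return law.vmax * atp * protein / denom


@dataclass(frozen=True)
class VEGFSynthesisLaw:
    """VEGF synthesis modulated by the relative HIF-driven mRNA level.

    ``k_syn = k_syn_original · ([mRNA]/[mRNA₀])^k_alpha`` where mRNA₀ is
    the normoxic mRNA baseline.  ``k_alpha`` defaults to 2, amplifying
    protein output relative to transcript fold-change.
    """

    k_syn_original: float
    k_alpha: float = 2.0
    mrna0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k_syn_original < 0:
            raise ValueError("k_syn_original must be >= 0")
        if self.k_alpha <= 0:
            raise ValueError("k_alpha must be > 0")
        if self.mrna0 is not None and self.mrna0 <= 0:
            raise ValueError("mrna0 must be > 0 once set")


def vegf_synthesis_rate(mrna: float, law: VEGFSynthesisLaw) -> float:
    """Synthesis rate ``k_syn_original · (mRNA/mRNA₀)^k_alpha``.

    Equals ``k_syn_original`` exactly at the normoxic baseline and 0 at
    zero mRNA.
    """
    if law.mrna0 is None or law.mrna0 <= 0:
        raise ValueError("VEGFSynthesisLaw.mrna0 must be configured (> 0)")
    if mrna < 0:
        raise ValueError(f"mrna must be >= 0, got {mrna}")
    if mrna == law.mrna0:
        return law.k_syn_original
    return law.k_syn_original * math.pow(mrna / law.mrna0, law.k_alpha)


@dataclass(frozen=True)
class VEGFBindingLaw:
    """Reversible VEGF–VEGFR association with inhibitable forward step."""

    k1f: float
    k1r: float

    def __post_init__(self) -> None:
        if self.k1f < 0 or self.k1r < 0:
            raise ValueError("binding rate constants must be >= 0")


def vegf_binding_rate(
    vegf: float,
    vegfr: float,
    vvegfr: float,
    d_over_ki: float,
    law: VEGFBindingLaw,
) -> float:
    """Net VEGF–VEGFR binding rate with competitive binding inhibitor.

    ``rate = k1f·[VEGF]·[VEGFR]/(1 + [D]/K_i) − k1r·[VVEGFR]``.
    Only the association term is inhibited; dissociation of pre-formed
    complex proceeds unhindered, so at saturating drug the net rate tends
    to ``−k1r·[VVEGFR]``.
    """
    if d_over_ki < 0:
        raise ValueError(f"d_over_ki must be >= 0, got {d_over_ki}")
    if min(vegf, vegfr, vvegfr) < 0:
        raise ValueError("concentrations must be >= 0")
    return law.k1f * vegf * vegfr / (1.0 + d_over_ki) - law.k1r * vvegfr
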