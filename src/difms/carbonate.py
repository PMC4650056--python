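"""Seawater CO2-system speciation from salinity, temperature, pH and pCO2.

Solves the experimental seawater's carbonate system the way marine-CO2
calculators do when handed a measured pH and an equilibration pCO2: CO2* is
set by Henry's law (with the Weiss virial fugacity correction), the
carbonate species follow from the dissociation constants at the measured
pH, and total alkalinity collects carbonate, borate, water and the minor
acid–base terms. Saturation states are Ω_x = [Ca2+][CO3 2−]/Ksp_x.

Default constant formulations (all at 0 dbar, reported pH fed directly to
total-scale constants):

* K1, K2 — Lueker et al. (2000), total scale
* K0 — Weiss (1974); fugacity correction from the same virial fit
* KB — Dickson (1990b); KS — Dickson (1990a); KF — Perez & Fraga (1987)
* KW — Millero (1995), total scale
* Ksp (calcite, aragonite) — Mucci (1983)
* Total boron — Uppström (1974); sulfate, fluoride, calcium scale with S/35

Concentrations are mol/kg-solution; TA is reported in μmol/kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

GAS_CONSTANT_CM3_ATM = 82.05746  # cm3 atm / (mol K)


@dataclass(frozen=True)
class CarbonateInput:
    salinity: float          # practical salinity
    temperature: float       # °C
    ph: float                # as reported; interpreted on the total scale
    pco2: float              # μatm
    pressure: float = 0.0    # dbar; only surface (0) is supported

    def __post_init__(self):
        if not 0 < self.salinity < 45:
            raise ValueError(f"salinity {self.salinity} outside (0, 45)")
        if not -2 < self.temperature < 40:
            raise ValueError(f"temperature {self.temperature} outside (-2, 40)")
        if not 2 < self.ph < 12:
            raise ValueError(f"pH {self.ph} outside (2, 12)")
        if self.pco2 <= 0:
            raise ValueError("pCO2 must be > 0")
        if self.pressure != 0:
            raise ValueError("only surface pressure (0 dbar) is supported")


@dataclass(frozen=True)
class CarbonateConstants:
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    Ksp_aragonite: float
    Ksp_calcite: float
    total_boron: float
    total_sulfate: float
    total_fluoride: float
    total_calcium: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not self.K1 > self.K2:
            raise ValueError("K1 must exceed K2")


@dataclass(frozen=True)
class CarbonateState:
    h: float            # total-scale proton concentration, mol/kg
    co2_star: float     # dissolved CO2 (+ H2CO3), mol/kg
    hco3: float
    co3: float
    dic: float
    ta: float           # μmol/kg
    omega_ar: float
    omega_cal: float


def compute_constants(inp: CarbonateInput) -> CarbonateConstants:
    """Equilibrium constants and conservative totals at (S, T, 0 dbar)."""
    S, T_C = inp.salinity, inp.temperature
    if not (19 < S < 43 and 2 < T_C < 35):
        warnings.warn("inputs outside the Lueker et al. fit range; "
                      "constants are extrapolated", stacklevel=2)
    T = T_C + 273.15
    lnT, log10T = np.log(T), np.log10(T)

    lnK0 = (-60.2409 + 93.4517 * (100 / T) + 23.3585 * np.log(T / 100)
            + S * (0.023517 - 0.023656 * (T / 100) + 0.0047036 * (T / 100) ** 2))
    pK1 = 3633.86 / T - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S ** 2
    pK2 = 471.78 / T + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S ** 2
    lnKB = ((-8966.90 - 2890.53 * S ** 0.5 - 77.942 * S + 1.728 * S ** 1.5
             - 0.0996 * S ** 2) / T
            + 148.0248 + 137.1942 * S ** 0.5 + 1.62142 * S
            + (-24.4344 - 25.085 * S ** 0.5 - 0.2474 * S) * lnT
            + 0.053105 * S ** 0.5 * T)
    lnKW = (148.9652 - 13847.26 / T - 23.6521 * lnT
            + (118.67 / T - 5.977 + 1.0495 * lnT) * S ** 0.5 - 0.01615 * S)
    I = 19.924 * S / (1000 - 1.005 * S)  # ionic strength, mol/kg-H2O
    lnKS = (-4276.1 / T + 141.328 - 23.093 * lnT
            + (-13856 / T + 324.57 - 47.986 * lnT) * I ** 0.5
            + (35474 / T - 771.54 + 114.723 * lnT) * I
            - 2698 / T * I ** 1.5 + 1776 / T * I ** 2
            + np.log(1 - 0.001005 * S))
    lnKF = 874 / T - 9.68 + 0.111 * S ** 0.5
    logKsp_cal = (-171.9065 - 0.077993 * T + 2839.319 / T + 71.595 * log10T
                  + (-0.77712 + 0.0028426 * T + 178.34 / T) * S ** 0.5
                  - 0.07711 * S + 0.0041249 * S ** 1.5)
    logKsp_ar = (-171.945 - 0.077993 * T + 2903.293 / T + 71.595 * log10T
                 + (-0.068393 + 0.0017276 * T + 88.135 / T) * S ** 0.5
                 - 0.10018 * S + 0.0059415 * S ** 1.5)

    return CarbonateConstants(
        K0=float(np.exp(lnK0)),
        K1=float(10 ** -pK1),
        K2=float(10 ** -pK2),
        KB=float(np.exp(lnKB)),
        KW=float(np.exp(lnKW)),
        KS=float(np.exp(lnKS)),
        KF=float(np.exp(lnKF)),
        Ksp_calcite=float(10 ** logKsp_cal),
        Ksp_aragonite=float(10 ** logKsp_ar),
        total_boron=0.0004157 * S / 35,
        total_sulfate=0.02824 * S / 35,
        total_fluoride=6.832e-5 * S / 35,
        total_calcium=0.01028 * S / 35,
    )


def fugacity_coefficient(temperature_c: float) -> float:
    """fCO2/pCO2 at 1 atm total pressure (Weiss 1974 virial expression)."""
    T = temperature_c + 273.15
    B = -1636.75 + 12.0408 * T - 0.0327957 * T ** 2 + 3.16528e-5 * T ** 3
    delta = 57.7 - 0.118 * T
    return float(np.exp((B + 2 * delta) / (GAS_CONSTANT_CM3_ATM * T)))


def _alkalinity(h: float, co2_star: float, k: CarbonateConstants) -> float:
    """TA (mol/kg) at total-scale [H+] with CO2* fixed."""
    hco3 = k.K1 * co2_star / h
    co3 = k.K1 * k.K2 * co2_star / h ** 2
    h_free = h / (1 + k.total_sulfate / k.KS)
    borate = k.total_boron * k.KB / (k.KB + h)
    oh = k.KW / h
    hso4 = k.total_sulfate / (1 + k.KS / h_free)
    hf = k.total_fluoride / (1 + k.KF / h)
    return hco3 + 2 * co3 + borate + oh - h_free - hso4 - hf


def solve_from_ph_pco2(inp: CarbonateInput,
                       constants: CarbonateConstants | None = None,
                       apply_fugacity: bool = True) -> CarbonateState:
    """Full speciation from (S, T, pH, pCO2)."""
    k = constants if constants is not None else compute_constants(inp)
    fco2_atm = inp.pco2 * 1e-6
    if apply_fugacity:
        fco2_atm *= fugacity_coefficient(inp.temperature)
    co2_star = k.K0 * fco2_atm
    h = 10.0 ** -inp.ph
    hco3 = k.K1 * co2_star / h
    co3 = k.K1 * k.K2 * co2_star / h ** 2
    dic = co2_star + hco3 + co3
    ta = _alkalinity(h, co2_star, k)
    omega_ar = k.total_calcium * co3 / k.Ksp_aragonite
    omega_cal = k.total_calcium * co3 / k.Ksp_calcite
    return CarbonateState(h=h, co2_star=co2_star, hco3=hco3, co3=co3,
                          dic=dic, ta=ta * 1e6,
                          omega_ar=omega_ar, omega_cal=omega_cal)


def ph_from_dic_ta(dic: float, ta_umol: float, k: CarbonateConstants) -> float:
    """Recover total-scale pH from (DIC, TA) by bracketed root finding."""
    ta = ta_umol * 1e-6

    def residual(ph: float) -> float:
        h = 10.0 ** -ph
        co2_star = dic / (1 + k.K1 / h + k.K1 * k.K2 / h ** 2)
        return _alkalinity(h, co2_star, k) - ta

    lo, hi = 2.0, 12.0
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise ValueError("no pH root in [2, 12] for the given (DIC, TA)")
    return float(brentq(residual, lo, hi, xtol=1e-10))


def round_trip_check(state: CarbonateState, inp: CarbonateInput,
                     constants: CarbonateConstants | None = None) -> float:
    """|pH recovered from (DIC, TA) − input pH|; a self-consistency residual."""
    k = constants if constants is not None else compute_constants(inp)
    return abs(ph_from_dic_ta(state.dic, state.ta, k) - inp.ph)
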