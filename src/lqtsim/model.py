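"""O'Hara–Rudy (ORd) human ventricular myocyte model with conductance-scaling hooks.

Implements the endocardial and epicardial variants of the ORd ionic model as a
41-state ODE system.  Six maximal conductances/permeabilities (G_Ks, G_Kr,
P_CaL, G_NCX, P_NaK, G_NaL) carry multiplicative scaling factors so that the
same right-hand side serves baseline simulations, long-QT conductance
perturbations, genetic-algorithm candidates and Hill-equation drug block.  A
seventh multiplier on the fast sodium conductance (G_Na) exists only for drug
block and is never an optimisation parameter.

The state layout (index -> name) is fixed by :data:`STATE_NAMES`; gating
variables live in [0, 1], concentrations are in mM, voltage in mV, time in ms,
currents in uA/uF.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "CellVariant",
    "ScalingFactors",
    "STATE_NAMES",
    "CURRENT_NAMES",
    "N_STATES",
    "derivatives",
    "currents",
]


class CellVariant(str, enum.Enum):
    """Transmural cell type. Only the two variants used here are supported."""

    ENDO = "endocardial"
    EPI = "epicardial"


def _as_variant(variant) -> "CellVariant":
    if isinstance(variant, CellVariant):
        return variant
    try:
        return CellVariant(variant)
    except ValueError:
        if str(variant).lower() in ("endo", "endocardial"):
            return CellVariant.ENDO
        if str(variant).lower() in ("epi", "epicardial"):
            return CellVariant.EPI
        raise ValueError(f"unknown cell variant: {variant!r}")


@dataclass(frozen=True)
class ScalingFactors:
    """Multiplicative scalings on baseline maximal conductances.

    ``ks, kr, cal, ncx, nak, nal`` scale G_Ks, G_Kr, P_CaL, G_NCX, P_NaK and
    G_NaL linearly (doubling a factor doubles that current at fixed state).
    ``nal_lqt3`` is inert in ordinary simulations; under the LQT3 condition the
    effective late-sodium multiplier becomes ``nal * nal_lqt3``.  ``na`` is the
    fast-sodium (G_Na) multiplier used by drug block only.
    """

    ks: float = 1.0
    kr: float = 1.0
    cal: float = 1.0
    ncx: float = 1.0
    nak: float = 1.0
    nal: float = 1.0
    nal_lqt3: float = 1.0
    na: float = 1.0

    def __post_init__(self):
        for name in ("ks", "kr", "cal", "ncx", "nak", "nal", "nal_lqt3", "na"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"scaling factor {name} must be positive and finite, got {value}")

    def with_(self, **kwargs) -> "ScalingFactors":
        return replace(self, **kwargs)

    def as_params(self, variant) -> np.ndarray:
        """Pack into the parameter vector consumed by the jitted kernels."""
        v = _as_variant(variant)
        return np.array(
            [1.0 if v is CellVariant.EPI else 0.0,
             self.ks, self.kr, self.cal, self.ncx, self.nak, self.nal, self.na],
            dtype=np.float64,
        )


STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(STATE_NAMES)

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab",
    "Jrel", "Jup", "Jdiff",
)
N_CURRENTS = len(CURRENT_NAMES)

# physical constants and cell geometry (ORd)
_R = 8314.0
_T = 310.0
_F = 96485.0
_NAO = 140.0
_CAO = 1.8
_KO = 5.4
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


@njit(cache=True, fastmath=False)
def _exp_flux(x, num_hi, num_lo):
    """(num_hi*e^x - num_lo) / (e^x - 1); callers branch to the limit near x=0."""
    return (num_hi * math.exp(x) - num_lo) / (math.exp(x) - 1.0)


@njit(cache=True, fastmath=False)
def _rates(y, p, istim, rate, inf, tau, cur):
    """Fill state rates, gate (inf, tau) pairs and current densities.

    ``tau[i] > 0`` marks states updatable by exact exponential (Rush-Larsen)
    integration: ordinary gates plus nca and the two SR-release fluxes, whose
    kinetics are linear in the state.  Everything else (voltage,
    concentrations, CaMKt) carries ``tau[i] = -1`` and is advanced explicitly.
    """
    epi = p[0] > 0.5
    s_ks, s_kr, s_cal, s_ncx, s_nak, s_nal, s_na = p[1], p[2], p[3], p[4], p[5], p[6], p[7]

    v = y[0]
    nai, nass = y[1], y[2]
    ki, kss = y[3], y[4]
    cai, cass = y[5], y[6]
    cansr, cajsr = y[7], y[8]
    m, hf, hs, j, hsp, jp = y[9], y[10], y[11], y[12], y[13], y[14]
    mL, hL, hLp = y[15], y[16], y[17]
    a, iF, iS, ap, iFp, iSp = y[18], y[19], y[20], y[21], y[22], y[23]
    d, ff, fs, fcaf, fcas, jca, nca, ffp, fcafp = (
        y[24], y[25], y[26], y[27], y[28], y[29], y[30], y[31], y[32])
    xrf, xrs, xs1, xs2, xk1 = y[33], y[34], y[35], y[36], y[37]
    Jrelnp, Jrelp, CaMKt = y[38], y[39], y[40]

    for i in range(41):
        tau[i] = -1.0
        inf[i] = 0.0

    # CaMK signalling
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    rate[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    # reversal potentials
    ENa = (_R * _T / _F) * math.log(_NAO / nai)
    EK = (_R * _T / _F) * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = (_R * _T / _F) * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vfrt = v * _F / (_R * _T)
    vffrt = vfrt * _F

    # --- fast sodium current INa ---
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    inf[9], tau[9] = mss, tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285) + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05) + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    inf[10], tau[10] = hss, thf
    inf[11], tau[11] = hss, ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281) + 0.3052 * math.exp((v + 0.9941) / 38.45))
    inf[12], tau[12] = jss, tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    inf[13], tau[13] = hssp, thsp
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    inf[14], tau[14] = jss, tjp
    GNa = 75.0 * s_na
    fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fINap) * h * j + fINap * hp * jp)

    # --- late sodium current INaL ---
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    inf[15], tau[15] = mLss, tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    inf[16], tau[16] = hLss, thL
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    inf[17], tau[17] = hLssp, thLp
    GNaL = 0.0075 * s_nal
    if epi:
        GNaL *= 0.6
    fINaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fINaLp) * hL + fINaLp * hLp)

    # --- transient outward current Ito ---
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    inf[18], tau[18] = ass, ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if epi:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    inf[19], tau[19] = iss, tiF
    inf[20], tau[20] = iss, tiS
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    inf[21], tau[21] = assp, ta
    dti_develop = 1.354 + 1e-4 / (math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    inf[22], tau[22] = iss, tiFp
    inf[23], tau[23] = iss, tiSp
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02
    if epi:
        Gto *= 4.0
    fItop = 1.0 / (1.0 + KmCaMK / CaMKa)
    Ito = Gto * (v - EK) * ((1.0 - fItop) * a * i_gate + fItop * ap * ip)

    # --- L-type calcium current ICaL (+ Na, K components through the channel) ---
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    inf[24], tau[24] = dss, td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    inf[25], tau[25] = fss, tff
    inf[26], tau[26] = fss, tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    inf[27], tau[27] = fcass, tfcaf
    inf[28], tau[28] = fcass, tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    inf[29], tau[29] = fcass, 75.0
    tffp = 2.5 * tff
    inf[31], tau[31] = fss, tffp
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    inf[32], tau[32] = fcass, tfcafp
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # dnca = anca*k2n - nca*km2n, linear in nca
    inf[30], tau[30] = anca * k2n / km2n, 1.0 / km2n
    PhiCaL = 4.0 * vffrt * _exp_flux(2.0 * vfrt, cass, 0.341 * _CAO) if abs(vfrt) >= 1e-7 else \
        2.0 * _F * (cass - 0.341 * _CAO)
    PhiCaNa = vffrt * _exp_flux(vfrt, 0.75 * nass, 0.75 * _NAO) if abs(vfrt) >= 1e-7 else \
        _F * 0.75 * (nass - _NAO)
    PhiCaK = vffrt * _exp_flux(vfrt, 0.75 * kss, 0.75 * _KO) if abs(vfrt) >= 1e-7 else \
        _F * 0.75 * (kss - _KO)
    PCa = 0.0001 * s_cal
    if epi:
        PCa *= 1.2
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    ICaL = ((1.0 - fICaLp) * PCa * PhiCaL * d * (f * (1.0 - nca) + jca * fca * nca)
            + fICaLp * PCap * PhiCaL * d * (fp * (1.0 - nca) + jca * fcap * nca))
    ICaNa = ((1.0 - fICaLp) * PCaNa * PhiCaNa * d * (f * (1.0 - nca) + jca * fca * nca)
             + fICaLp * PCaNap * PhiCaNa * d * (fp * (1.0 - nca) + jca * fcap * nca))
    ICaK = ((1.0 - fICaLp) * PCaK * PhiCaK * d * (f * (1.0 - nca) + jca * fca * nca)
            + fICaLp * PCaKp * PhiCaK * d * (fp * (1.0 - nca) + jca * fcap * nca))

    # --- rapid delayed rectifier IKr ---
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    inf[33], tau[33] = xrss, txrf
    inf[34], tau[34] = xrss, txrs
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + math.exp((v + 55.0) / 75.0)) / (1.0 + math.exp((v - 10.0) / 30.0))
    GKr = 0.046 * s_kr
    if epi:
        GKr *= 1.3
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # --- slow delayed rectifier IKs ---
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    inf[35], tau[35] = xs1ss, txs1
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    inf[36], tau[36] = xs1ss, txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * s_ks
    if epi:
        GKs *= 1.4
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # --- inward rectifier IK1 ---
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * _KO + 144.59) / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    inf[37], tau[37] = xk1ss, txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908
    if epi:
        GK1 *= 1.2
    IK1 = GK1 * math.sqrt(_KO) * rk1 * xk1 * (v - EK)

    # --- sodium-calcium exchange INaCa (myoplasmic and subspace) ---
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    Gncx = 0.0008 * s_ncx
    if epi:
        Gncx *= 1.1
    KmCaAct = 150.0e-6

    # myoplasmic compartment
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # subspace compartment
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * _CAO * kcaon
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

    # --- sodium-potassium pump INaK ---
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (_NAO / Knao) ** 3) / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0)
    a3 = (k3p_ * (_KO / Kko) ** 2) / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p_ * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * s_nak
    if epi:
        Pnak *= 0.9
    INaK = Pnak * (JnakNa + JnakK)

    # --- background and pump currents ---
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if epi:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    if abs(vfrt) >= 1e-7:
        INab = 3.75e-10 * vffrt * _exp_flux(vfrt, nai, _NAO)
        ICab = 2.5e-8 * 4.0 * vffrt * _exp_flux(2.0 * vfrt, cai, 0.341 * _CAO)
    else:
        INab = 3.75e-10 * _F * (nai - _NAO)
        ICab = 2.5e-8 * 2.0 * _F * (cai - 0.341 * _CAO)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- diffusion fluxes between subspace and myoplasm ---
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- SR calcium release (RyR), CaMK-phosphorylated and not ---
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    inf[38], tau[38] = Jrel_inf, tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    inf[39], tau[39] = Jrel_infp, tau_relp
    fJrelp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jrel = (1.0 - fJrelp) * Jrelnp + fJrelp * Jrelp

    # --- SR calcium uptake (SERCA) and translocation ---
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if epi:
        Jupnp *= 1.3
        Jupp *= 1.3
    fJupp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- membrane potential ---
    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)
    rate[0] = -Itot

    # --- ionic concentrations ---
    cmdnmax = 0.05
    if epi:
        cmdnmax *= 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    rate[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * _ACAP / (_F * _VMYO) \
        + JdiffNa * _VSS / _VMYO
    rate[2] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    rate[3] = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) * _ACAP / (_F * _VMYO) \
        + JdiffK * _VSS / _VMYO
    rate[4] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2 + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    rate[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                      - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2 + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    rate[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                       + Jrel * _VJSR / _VSS - Jdiff)
    rate[7] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    rate[8] = Bcajsr * (Jtr - Jrel)

    # gate rates from (inf, tau) for completeness of the derivative vector
    for i in range(9, 40):
        rate[i] = (inf[i] - y[i]) / tau[i]

    cur[0] = INa
    cur[1] = INaL
    cur[2] = Ito
    cur[3] = ICaL
    cur[4] = ICaNa
    cur[5] = ICaK
    cur[6] = IKr
    cur[7] = IKs
    cur[8] = IK1
    cur[9] = INaCa_i
    cur[10] = INaCa_ss
    cur[11] = INaK
    cur[12] = INab
    cur[13] = IKb
    cur[14] = IpCa
    cur[15] = ICab
    cur[16] = Jrel
    cur[17] = Jup
    cur[18] = Jdiff


def _validate_state(state: np.ndarray) -> np.ndarray:
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite entries")
    return y


def derivatives(variant, scalings: ScalingFactors, state, stim_current: float = 0.0) -> np.ndarray:
    """Time-derivatives of the full state vector (units per ms).

    ``stim_current`` is an applied current density in uA/uF (negative =
    depolarising) added to the membrane equation and to the K+ balance, as in
    the published model.
    """
    y = _validate_state(state)
    p = scalings.as_params(variant)
    rate = np.empty(N_STATES)
    inf = np.empty(N_STATES)
    tau = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    _rates(y, p, float(stim_current), rate, inf, tau, cur)
    return rate


def currents(variant, scalings: ScalingFactors, state, stim_current: float = 0.0) -> dict:
    """Individual current densities (uA/uF) and SR fluxes (mM/ms) at a state."""
    y = _validate_state(state)
    p = scalings.as_params(variant)
    rate = np.empty(N_STATES)
    inf = np.empty(N_STATES)
    tau = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    _rates(y, p, float(stim_current), rate, inf, tau, cur)
    return dict(zip(CURRENT_NAMES, cur))
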