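"""Spontaneous hiPSC-cardiomyocyte action-potential model with a late Na+ current.

The baseline electrophysiology is the ventricular-like human induced
pluripotent stem cell-derived cardiomyocyte (hiPSC-CM) model of Paci,
Hyttinen, Aalto-Setala and Severi (Ann Biomed Eng 41:2334-2348, 2013),
a Hodgkin-Huxley style membrane model with 11 sarcolemmal currents,
dynamic intracellular Na+ and Ca2+ (cytosolic and sarcoplasmic-reticulum)
concentrations, and spontaneous (unstimulated) beating.  On top of it we
add a late sodium current I_NaL in Hodgkin-Huxley form (activation gate
``mL`` with fast kinetics, slow inactivation gate ``hL``), the gating
shapes following O'Hara and Rudy (PLoS Comput Biol 7:e1002061, 2011).

Long QT syndrome type 3 (LQT3) gain-of-function of the Na+ channel is
represented by the ``V1763M`` genotype: the mutant I_NaL carries a
depolarizing shift of the ``hL`` steady-state inactivation curve, a slowed
inactivation time constant and a conductance scale, calibrated so that the
persistent I_NaL sampled 200 ms after the upstroke of the steady-state
spontaneous AP is 4.86-fold the control value (see
:data:`MUTANT_HL_SHIFT_MV`, :data:`MUTANT_TAU_HL_SCALE`,
:data:`MUTANT_GNAL_SCALE`).

Unit conventions
----------------
Voltage is handled internally in **volts** (the native convention of the
source model; all sigmoidal rate laws convert to mV internally).  Currents
are in A/F (normalised by membrane capacitance), conductances in S/F,
the L-type Ca2+ permeability in m^3/(F*s), concentrations in mM, time in
seconds.  Conversion to the mV / ms conventions used for biomarkers
happens at the :class:`~cardiopop.simulation.Trace` boundary.

Equation provenance: every current block below is transcribed from the
2013 publication's supplement (ventricular variant); the I_NaL block from
the O'Hara-Rudy endocardial formulation with the maximal conductance and
mutant parameters calibrated here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

__all__ = [
    "Genotype",
    "CellParameters",
    "CellState",
    "CurrentSet",
    "BlockFactors",
    "BASELINE_MAXIMA",
    "SAMPLED_PARAMETERS",
    "compute_currents",
    "derivatives",
    "apply_mutation",
    "initial_state",
    "CURRENT_NAMES",
    "STATE_NAMES",
]

# ---------------------------------------------------------------------------
# Physical constants and cell geometry (fixed, never sampled)
# ---------------------------------------------------------------------------

F = 96485.3415        # C/mol
R_GAS = 8.314472      # J/(mol K)
T = 310.0             # K
CM = 9.87109e-11      # F, membrane capacitance
VC = 8800.0           # um^3, cytosolic volume
V_SR = 583.73         # um^3, sarcoplasmic reticulum volume

# External / fixed ionic concentrations (mM)
NAO = 151.0
KO = 5.4
CAO = 1.8
KI = 150.0            # intracellular K+ held constant (source-model choice)

PK_NA = 0.03          # Na+ permeability fraction of IKs reversal
E_F = -0.017          # V, reversal of the funny current

# Ca2+ handling constants
A_REL = 16.464        # mM/s
B_REL = 0.25          # mM
C_REL = 8.232         # mM/s
V_MAX_UP = 0.56064    # mM/s
K_UP = 2.5e-4         # mM
V_LEAK = 4.4444e-4    # 1/s
BUF_C = 0.25          # mM
K_BUF_C = 0.001       # mM
BUF_SR = 10.0         # mM
K_BUF_SR = 0.3        # mM

# NaK / NCX / pCa constants
KM_K = 1.0            # mM
KM_NA = 40.0          # mM
K_NACA_SAT = 0.1
ALPHA_NACA = 2.8571432
GAMMA_NACA = 0.35
KM_CA = 1.38          # mM
KM_NAI = 87.5         # mM
K_PCA = 0.0005        # mM

# ---------------------------------------------------------------------------
# Baseline maximal conductances / permeabilities (the sampled maxima)
# ---------------------------------------------------------------------------

#: The 11 maxima varied when building a population, with baseline values.
#: g_* in S/F, P_CaL in m^3/(F*s), k_NCX / P_NaK / g_pCa in A/F.
BASELINE_MAXIMA = {
    "g_Na": 3671.2302,
    "g_NaL": 46.4,           # calibrated here (see module docstring)
    "P_CaL": 8.635702e-5,
    "g_Kr": 29.8667,
    "g_Ks": 2.041,
    "g_K1": 28.1492,
    "g_f": 30.10312,
    "g_to": 29.9038,
    "k_NCX": 4900.0,
    "P_NaK": 1.841424,
    "g_pCa": 0.4125,
}

SAMPLED_PARAMETERS = tuple(BASELINE_MAXIMA)

# Background conductances (fixed in the population method)
G_B_NA = 0.9          # S/F
G_B_CA = 0.69264      # S/F

# Mutant (V1763M) late-Na parameters, calibrated against the observable
# constraints: persistent-I_NaL ratio 4.86 at 200 ms post-upstroke and
# ~+43% APD90 prolongation of the baseline mutant vs baseline control.
MUTANT_HL_SHIFT_MV = 12.5
MUTANT_TAU_HL_SCALE = 2.0
MUTANT_GNAL_SCALE = 0.766


class Genotype(str, enum.Enum):
    """Na+-channel genotype of a model variant."""

    CONTROL = "control"
    V1763M = "V1763M"


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances/permeabilities of the sarcolemmal currents.

    The 11 maxima are the quantities multiplied by the population scale
    factors; everything else about the cell (kinetics, geometry, fixed
    concentrations) is shared by all models and lives in module constants.
    """

    g_Na: float = BASELINE_MAXIMA["g_Na"]
    g_NaL: float = BASELINE_MAXIMA["g_NaL"]
    P_CaL: float = BASELINE_MAXIMA["P_CaL"]
    g_Kr: float = BASELINE_MAXIMA["g_Kr"]
    g_Ks: float = BASELINE_MAXIMA["g_Ks"]
    g_K1: float = BASELINE_MAXIMA["g_K1"]
    g_f: float = BASELINE_MAXIMA["g_f"]
    g_to: float = BASELINE_MAXIMA["g_to"]
    k_NCX: float = BASELINE_MAXIMA["k_NCX"]
    P_NaK: float = BASELINE_MAXIMA["P_NaK"]
    g_pCa: float = BASELINE_MAXIMA["g_pCa"]
    g_b_Na: float = G_B_NA
    g_b_Ca: float = G_B_CA
    genotype: Genotype = Genotype.CONTROL

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        for f in fields(self):
            if f.name == "genotype":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_scale_factors(
        cls, scales: dict[str, float], genotype: Genotype | str = Genotype.CONTROL
    ) -> "CellParameters":
        """Build parameters from multiplicative scale factors on the baseline maxima."""
        unknown = set(scales) - set(SAMPLED_PARAMETERS)
        if unknown:
            raise KeyError(f"unknown sampled parameters: {sorted(unknown)}")
        values = {k: BASELINE_MAXIMA[k] * scales.get(k, 1.0) for k in SAMPLED_PARAMETERS}
        return cls(genotype=Genotype(genotype), **values)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["genotype"] = self.genotype.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellParameters":
        return cls(**d)

    def pack(self, blocks: "BlockFactors | None" = None) -> np.ndarray:
        """Flatten to the parameter vector consumed by the jitted kernels."""
        b = blocks if blocks is not None else BlockFactors()
        b.validate()
        mutant = self.genotype is Genotype.V1763M
        return np.array(
            [
                self.g_Na,
                self.g_NaL * (MUTANT_GNAL_SCALE if mutant else 1.0),
                self.P_CaL,
                self.g_Kr,
                self.g_Ks,
                self.g_K1,
                self.g_f,
                self.g_to,
                self.k_NCX,
                self.P_NaK,
                self.g_pCa,
                self.g_b_Na,
                self.g_b_Ca,
                b.i_na,
                b.i_nal,
                b.i_kr,
                b.i_cal,
                MUTANT_HL_SHIFT_MV if mutant else 0.0,
                MUTANT_TAU_HL_SCALE if mutant else 1.0,
            ],
            dtype=np.float64,
        )


def apply_mutation(params: CellParameters) -> CellParameters:
    """Return the V1763M variant of ``params`` (idempotent).

    Only the genotype flag changes: the mutant late-Na formulation (shifted
    ``hL`` inactivation, scaled conductance) is keyed off the genotype, so
    every sampled scale factor is preserved — the in-silico analogue of
    transfecting the mutation into an existing cell.
    """
    if params.genotype is Genotype.V1763M:
        return params
    return replace(params, genotype=Genotype.V1763M)


@dataclass
class BlockFactors:
    """Multiplicative conductance scalings in [0, 1] applied by a pore-block drug.

    ``1.0`` means no block.  Only the four drug-targeted channels are
    scalable; all other currents are never blocked.
    """

    i_na: float = 1.0
    i_nal: float = 1.0
    i_kr: float = 1.0
    i_cal: float = 1.0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"block factor {f.name}={v!r} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "Vm",      # membrane voltage, V
    "m", "h", "j",                 # I_Na gates
    "d", "f1", "f2", "fCa",        # I_CaL gates
    "Xr1", "Xr2",                  # I_Kr gates
    "Xs",                          # I_Ks gate
    "Xf",                          # I_f gate
    "q", "r",                      # I_to gates
    "g_ryr",                       # SR release gate
    "mL", "hL",                    # I_NaL gates
    "Nai", "Cai", "Ca_SR",         # concentrations, mM
)
N_STATES = len(STATE_NAMES)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
_GATE_SLICE = slice(1, 17)
_CONC_SLICE = slice(17, 20)


@dataclass
class CellState:
    """Named view over the 20-component model state vector."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.shape != (N_STATES,):
            raise ValueError(f"state vector must have shape ({N_STATES},)")

    def __getattr__(self, name):
        try:
            return self.y[_IDX[name]]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def Vm_mV(self) -> float:
        return float(self.y[0]) * 1000.0

    def validate(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise FloatingPointError("non-finite cell state")
        gates = self.y[_GATE_SLICE]
        if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(self.y[_CONC_SLICE] <= 0):
            raise ValueError("non-positive ionic concentration")

    def copy(self) -> "CellState":
        return CellState(self.y.copy())


CURRENT_NAMES = (
    "I_Na", "I_NaL", "I_CaL", "I_Kr", "I_Ks", "I_K1",
    "I_f", "I_to", "I_NCX", "I_NaK", "I_pCa", "I_bNa", "I_bCa",
)
N_CURRENTS = len(CURRENT_NAMES)


@dataclass(frozen=True)
class CurrentSet:
    """All sarcolemmal currents at one instant, A/F (inward negative)."""

    I_Na: float
    I_NaL: float
    I_CaL: float
    I_Kr: float
    I_Ks: float
    I_K1: float
    I_f: float
    I_to: float
    I_NCX: float
    I_NaK: float
    I_pCa: float
    I_bNa: float
    I_bCa: float

    def total(self) -> float:
        return float(sum(getattr(self, n) for n in CURRENT_NAMES))

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in CURRENT_NAMES}


# ---------------------------------------------------------------------------
# Jitted kernels.  p layout (see CellParameters.pack):
#  0 g_Na  1 g_NaL(eff)  2 P_CaL  3 g_Kr  4 g_Ks  5 g_K1  6 g_f  7 g_to
#  8 k_NCX  9 P_NaK  10 g_pCa  11 g_b_Na  12 g_b_Ca
#  13 block_Na  14 block_NaL  15 block_Kr  16 block_CaL
#  17 hL_shift_mV  18 tau_hL_scale
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _currents_kernel(y, p):
    V = y[0]
    v = V * 1000.0  # mV, used by the rate-law sigmoids
    Nai = y[17]
    Cai = y[18]

    rtf = R_GAS * T / F
    E_Na = rtf * math.log(NAO / Nai)
    E_K = rtf * math.log(KO / KI)
    E_Ks = rtf * math.log((KO + PK_NA * NAO) / (KI + PK_NA * Nai))
    E_Ca = 0.5 * rtf * math.log(CAO / Cai)

    out = np.empty(N_CURRENTS)
    # fast Na+
    out[0] = p[13] * p[0] * y[1] ** 3 * y[2] * y[3] * (V - E_Na)
    # late Na+
    out[1] = p[14] * p[1] * y[15] * y[16] * (V - E_Na)
    # L-type Ca2+ (GHK-like driving term)
    expv = math.exp(2.0 * V * F / (R_GAS * T))
    if abs(V) < 1e-9:
        drive = 2.0 * F * (Cai - 0.341 * CAO)  # limit of the GHK term at V=0
    else:
        drive = (4.0 * V * F * F / (R_GAS * T)) * (Cai * expv - 0.341 * CAO) / (expv - 1.0)
    out[2] = p[16] * p[2] * drive * y[4] * y[5] * y[6] * y[7]
    # rapid delayed rectifier
    out[3] = p[15] * p[3] * math.sqrt(KO / 5.4) * y[8] * y[9] * (V - E_K)
    # slow delayed rectifier with Ca2+ sensitivity
    out[4] = p[4] * y[10] * y[10] * (V - E_Ks) * (1.0 + 0.6 / (1.0 + (3.8e-5 / Cai) ** 1.4))
    # inward rectifier (instantaneous gating)
    vk = v - E_K * 1000.0
    a_k1 = 3.91 / (1.0 + math.exp(0.5942 * (vk - 200.0)))
    b_k1 = (-1.509 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.5886 * (vk - 10.0))) / (
        1.0 + math.exp(0.4547 * vk)
    )
    out[5] = p[5] * math.sqrt(KO / 5.4) * (a_k1 / (a_k1 + b_k1)) * (V - E_K)
    # funny current
    out[6] = p[6] * y[11] * (V - E_F)
    # transient outward
    out[7] = p[7] * y[12] * y[13] * (V - E_K)
    # Na+/Ca2+ exchanger
    efrac = math.exp(GAMMA_NACA * V * F / (R_GAS * T))
    efrac1 = math.exp((GAMMA_NACA - 1.0) * V * F / (R_GAS * T))
    out[8] = (
        p[8]
        * (efrac * Nai ** 3 * CAO - efrac1 * NAO ** 3 * Cai * ALPHA_NACA)
        / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_NACA_SAT * efrac1))
    )
    # Na+/K+ pump
    out[9] = (
        p[9]
        * (KO / (KO + KM_K))
        * (Nai / (Nai + KM_NA))
        / (1.0 + 0.1245 * math.exp(-0.1 * V * F / (R_GAS * T)) + 0.0353 * math.exp(-V * F / (R_GAS * T)))
    )
    # sarcolemmal Ca2+ pump
    out[10] = p[10] * Cai / (Cai + K_PCA)
    # backgrounds
    out[11] = p[11] * (V - E_Na)
    out[12] = p[12] * (V - E_Ca)
    return out


@njit(cache=True, fastmath=False)
def _rhs_kernel(t, y, p):
    V = y[0]
    v = V * 1000.0
    Cai = y[18]
    Ca_SR = y[19]

    cur = _currents_kernel(y, p)
    i_tot = 0.0
    for k in range(N_CURRENTS):
        i_tot += cur[k]

    dy = np.empty(N_STATES)
    dy[0] = -i_tot  # currents are A/F, so dV/dt in V/s

    # --- I_Na gates (TT04-derived kinetics of the source model) ---
    m_inf = 1.0 / (1.0 + math.exp((-v - 34.1) / 5.9)) ** (1.0 / 3.0)
    a_m = 1.0 / (1.0 + math.exp((-v - 60.0) / 5.0))
    b_m = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m / 1000.0
    dy[1] = (m_inf - y[1]) / tau_m

    h_inf = 1.0 / math.sqrt(1.0 + math.exp((v + 72.1) / 5.7))
    if v < -38.5:
        a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        tau_h = 1.5 / ((a_h + b_h) * 1000.0)
    else:
        tau_h = 1.5 * 1.6947 / 1000.0
    dy[2] = (h_inf - y[2]) / tau_h

    j_inf = h_inf
    if v < -40.0:
        a_j = (
            (-25428.0 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        b_j = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        a_j = 0.0
        b_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tau_j = 7.0 / ((a_j + b_j) * 1000.0)
    dy[3] = (j_inf - y[3]) / tau_j

    # --- I_CaL gates ---
    d_inf = 1.0 / (1.0 + math.exp(-(v + 9.1) / 7.0))
    a_d = 0.25 + 1.4 / (1.0 + math.exp((-v - 35.0) / 13.0))
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((-v + 50.0) / 20.0))
    tau_d = (a_d * b_d + g_d) / 1000.0
    dy[4] = (d_inf - y[4]) / tau_d

    f1_inf = 1.0 / (1.0 + math.exp((v + 26.0) / 3.0))
    if f1_inf - y[5] > 0.0:
        const_f1 = 1.0 + 1433.0 * (Cai - 50.0e-6)
    else:
        const_f1 = 1.0
    tau_f1 = (
        20.0
        + 1102.5 * math.exp(-(((v + 27.0) ** 2 / 15.0) ** 2))
        + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + math.exp((30.0 + v) / 10.0))
    ) * const_f1 / 1000.0
    dy[5] = (f1_inf - y[5]) / tau_f1

    f2_inf = 0.33 + 0.67 / (1.0 + math.exp((v + 35.0) / 4.0))
    tau_f2 = (
        600.0 * math.exp(-((v + 25.0) ** 2) / 170.0)
        + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
        + 16.0 / (1.0 + math.exp((30.0 + v) / 10.0))
    ) / 1000.0
    dy[6] = (f2_inf - y[6]) / tau_f2

    a_fca = 1.0 / (1.0 + (Cai / 0.0006) ** 8)
    b_fca = 0.1 / (1.0 + math.exp((Cai - 0.0009) / 0.0001))
    g_fca = 0.3 / (1.0 + math.exp((Cai - 0.00075) / 0.0008))
    fca_inf = (a_fca + b_fca + g_fca) / 1.3156
    if V > -0.06 and fca_inf > y[7]:
        dy[7] = 0.0  # Ca2+-dependent gate latched during depolarisation
    else:
        dy[7] = (fca_inf - y[7]) / 0.002

    # --- I_Kr gates ---
    L0 = 0.025
    v_half = 1000.0 * (
        -R_GAS * T / (F * 2.3) * math.log((1.0 + CAO / 2.6) ** 4 / (L0 * (1.0 + CAO / 0.58) ** 4))
        - 0.019
    )
    xr1_inf = 1.0 / (1.0 + math.exp((v_half - v) / 4.9))
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((30.0 + v) / 11.5))
    dy[8] = (xr1_inf - y[8]) / (a_xr1 * b_xr1 / 1000.0)

    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 50.0))
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((-60.0 + v) / 20.0))
    dy[9] = (xr2_inf - y[9]) / (a_xr2 * b_xr2 / 1000.0)

    # --- I_Ks gate ---
    xs_inf = 1.0 / (1.0 + math.exp((-v - 20.0) / 16.0))
    a_xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((-60.0 + v) / 20.0))
    dy[10] = (xs_inf - y[10]) / (a_xs * b_xs / 1000.0)

    # --- I_f gate ---
    xf_inf = 1.0 / (1.0 + math.exp((v + 77.85) / 5.0))
    tau_xf = 1900.0 / (1.0 + math.exp((v + 15.0) / 10.0)) / 1000.0
    dy[11] = (xf_inf - y[11]) / tau_xf

    # --- I_to gates ---
    q_inf = 1.0 / (1.0 + math.exp((v + 53.0) / 13.0))
    tau_q = (
        6.06 + 39.102 / (0.57 * math.exp(-0.08 * (v + 44.0)) + 0.065 * math.exp(0.1 * (v + 45.93)))
    ) / 1000.0
    dy[12] = (q_inf - y[12]) / tau_q

    r_inf = 1.0 / (1.0 + math.exp(-(v - 22.3) / 18.75))
    tau_r = (
        2.75352 + 14.40516 / (1.037 * math.exp(0.09 * (v + 30.61)) + 0.369 * math.exp(-0.12 * (v + 23.84)))
    ) / 1000.0
    dy[13] = (r_inf - y[13]) / tau_r

    # --- SR release gate ---
    if Cai <= 0.00035:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 16)
    if g_inf > y[14] and V > -0.06:
        dy[14] = 0.0
    else:
        dy[14] = (g_inf - y[14]) / 0.002

    # --- I_NaL gates (O'Hara-Rudy shapes; mutant shift on hL) ---
    mL_inf = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tau_mL = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955)) / 1000.0
    dy[15] = (mL_inf - y[15]) / tau_mL

    hL_inf = 1.0 / (1.0 + math.exp((v + 87.61 - p[17]) / 7.488))
    tau_hL = 0.200 * p[18]
    dy[16] = (hL_inf - y[16]) / tau_hL

    # --- concentrations ---
    conv = CM / (VC * F * 1.0e-18)  # A/F -> mM/s for the cytosolic volume
    dy[17] = -(cur[0] + cur[1] + cur[11] + 3.0 * cur[9] + 3.0 * cur[8]) * conv

    i_rel = (C_REL + A_REL * Ca_SR * Ca_SR / (B_REL * B_REL + Ca_SR * Ca_SR)) * y[4] * y[14] * 0.0411
    i_up = V_MAX_UP / (1.0 + (K_UP / Cai) ** 2)
    i_leak = (Ca_SR - Cai) * V_LEAK
    buf_c = 1.0 / (1.0 + BUF_C * K_BUF_C / (Cai + K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (Ca_SR + K_BUF_SR) ** 2)
    dy[18] = buf_c * (
        i_leak - i_up + i_rel - (cur[2] + cur[12] + cur[10] - 2.0 * cur[8]) * conv / 2.0
    )
    dy[19] = buf_sr * (VC / V_SR) * (i_up - i_rel - i_leak)
    return dy


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def _check_state(state: CellState) -> np.ndarray:
    y = state.y if isinstance(state, CellState) else np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite cell state passed to the model")
    return y


def compute_currents(
    state: CellState, params: CellParameters, blocks: BlockFactors | None = None
) -> CurrentSet:
    """Evaluate every sarcolemmal current at ``state`` (A/F, inward negative)."""
    y = _check_state(state)
    vals = _currents_kernel(y, params.pack(blocks))
    return CurrentSet(*[float(x) for x in vals])


def derivatives(
    t: float, state: CellState, params: CellParameters, blocks: BlockFactors | None = None
) -> np.ndarray:
    """Time derivative of the full state vector (V/s, 1/s, mM/s)."""
    y = _check_state(state)
    return _rhs_kernel(t, y, params.pack(blocks))


def gate_steady_state(v_mV: float, p: np.ndarray | None = None) -> dict[str, float]:
    """Voltage-dependent steady-state value of every gate at a clamped voltage.

    Useful for building initial conditions and for fixed-point checks of the
    Hodgkin-Huxley kinetics.  The Ca2+-dependent gates (``fCa``, ``g_ryr``)
    are evaluated at diastolic Cai.
    """
    v = v_mV
    cai = 2.0e-5
    out = {
        "m": 1.0 / (1.0 + math.exp((-v - 34.1) / 5.9)) ** (1.0 / 3.0),
        "h": 1.0 / math.sqrt(1.0 + math.exp((v + 72.1) / 5.7)),
        "j": 1.0 / math.sqrt(1.0 + math.exp((v + 72.1) / 5.7)),
        "d": 1.0 / (1.0 + math.exp(-(v + 9.1) / 7.0)),
        "f1": 1.0 / (1.0 + math.exp((v + 26.0) / 3.0)),
        "f2": 0.33 + 0.67 / (1.0 + math.exp((v + 35.0) / 4.0)),
        "Xr1": None,
        "Xr2": 1.0 / (1.0 + math.exp((v + 88.0) / 50.0)),
        "Xs": 1.0 / (1.0 + math.exp((-v - 20.0) / 16.0)),
        "Xf": 1.0 / (1.0 + math.exp((v + 77.85) / 5.0)),
        "q": 1.0 / (1.0 + math.exp((v + 53.0) / 13.0)),
        "r": 1.0 / (1.0 + math.exp(-(v - 22.3) / 18.75)),
        "mL": 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264)),
        "hL": 1.0 / (1.0 + math.exp((v + 87.61) / 7.488)),
    }
    L0 = 0.025
    v_half = 1000.0 * (
        -R_GAS * T / (F * 2.3) * math.log((1.0 + CAO / 2.6) ** 4 / (L0 * (1.0 + CAO / 0.58) ** 4))
        - 0.019
    )
    out["Xr1"] = 1.0 / (1.0 + math.exp((v_half - v) / 4.9))
    a = 1.0 / (1.0 + (cai / 0.0006) ** 8)
    b = 0.1 / (1.0 + math.exp((cai - 0.0009) / 0.0001))
    g = 0.3 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    out["fCa"] = (a + b + g) / 1.3156
    out["g_ryr"] = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    return out


def initial_state() -> CellState:
    """Published diastolic starting point of the baseline model.

    Gates at their steady-state values for the diastolic voltage; the
    simulation layer always pre-runs long enough that the limit cycle, not
    this point, determines reported biomarkers.
    """
    v0 = -0.0743  # V
    ss = gate_steady_state(v0 * 1000.0)
    y = np.empty(N_STATES)
    y[0] = v0
    for name in STATE_NAMES[1:17]:
        y[_IDX[name]] = min(1.0, max(0.0, ss[name]))
    y[_IDX["Nai"]] = 10.9
    y[_IDX["Cai"]] = 3.7e-5
    y[_IDX["Ca_SR"]] = 0.27
    return CellState(y)
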