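"""Numba-compiled right-hand side and Jacobian of the 14-state ODE system.

State vector layout (indices):

==  ===========  ====================================================
 0  B            inactive beta3-adrenergic receptors (a.u.)
 1  Bact         active receptors (a.u.)
 2  Bde          desensitized receptors (a.u.)
 3  cAMP         cytosolic cAMP above basal (mM)
 4  Ca           cytosolic free Ca2+ above basal (uM)
 5  ATP          cytosolic ATP above basal (mM)
 6  pipcAMP      pipette cAMP (mM)
 7  pipCa        pipette free Ca2+ (uM)
 8  pipATP       pipette ATP (mM)
 9  Res          reserve vesicle pool (a.u., constant)
10  Rel          releasable vesicle pool (a.u.)
11  PM           vesicles fused with the plasma membrane (a.u.)
12  Endo         membrane portion pending endocytosis (a.u.)
13  Adiponectin  cumulative released adiponectin (a.u.)
==  ===========  ====================================================

Time is in seconds here; the public API converts from minutes.
Parameter vector order matches ``parameters.PARAM_NAMES``.
"""

import numpy as np
from numba import njit

N_STATES = 14

STATE_NAMES = (
    "B", "Bact", "Bde", "cAMP", "Ca", "ATP",
    "pipcAMP", "pipCa", "pipATP",
    "Res", "Rel", "PM", "Endo", "Adiponectin",
)


@njit(cache=True)
def rhs(y, t, k, EPI, CL, pip):
    krel = k[0]; kexo = k[1]; kCaATP = k[2]; kcAMP = k[3]; kCa2 = k[4]
    kATP2 = k[5]; kEndo = k[6]; kCacAMP = k[7]; km = k[8]; kdegcAMP = k[9]
    kremCa = k[10]; kdegATP = k[11]; kDiffcAMP = k[12]; kDiffCa = k[13]
    kDiffATP = k[14]; kB = k[15]; kCL = k[16]; k1 = k[17]; k2 = k[18]
    k3 = k[19]; Vpip = k[20]; Vcell = k[21]

    B = y[0]; Bact = y[1]; Bde = y[2]; cAMP = y[3]; Ca = y[4]; ATP = y[5]
    pipcAMP = y[6]; pipCa = y[7]; pipATP = y[8]
    Res = y[9]; Rel = y[10]; PM = y[11]; Endo = y[12]

    activation = kB * B * (EPI + kCL * CL)
    vol_ratio = Vcell / Vpip
    flux_cAMP = kDiffcAMP * (pipcAMP - cAMP) * pip
    flux_Ca = kDiffCa * (pipCa - Ca) * pip
    flux_ATP = kDiffATP * (pipATP - ATP) * pip
    mm = Ca / (km + Ca)
    vRes_Rel = mm * (kCa2 + kATP2 * ATP) * Res
    vRel_PM = cAMP * (kcAMP + mm * ATP * kCaATP) * Rel

    out = np.empty(N_STATES)
    out[0] = k1 * Bde - activation
    out[1] = activation - Bact * k2
    out[2] = Bact * k2 - k1 * Bde
    out[3] = flux_cAMP + Bact * k3 - kdegcAMP * cAMP
    out[4] = flux_Ca - kremCa * Ca
    out[5] = flux_ATP - kdegATP * ATP
    out[6] = -flux_cAMP * vol_ratio
    out[7] = -flux_Ca * vol_ratio
    out[8] = -flux_ATP * vol_ratio
    out[9] = 0.0
    out[10] = vRes_Rel - vRel_PM + krel * PM
    out[11] = vRel_PM - krel * PM - kexo * PM
    out[12] = kCacAMP * cAMP * Ca - kEndo * Endo
    out[13] = kexo * PM
    return out


@njit(cache=True)
def jacobian(y, t, k, EPI, CL, pip):
    krel = k[0]; kexo = k[1]; kCaATP = k[2]; kcAMP = k[3]; kCa2 = k[4]
    kATP2 = k[5]; kEndo = k[6]; kCacAMP = k[7]; km = k[8]; kdegcAMP = k[9]
    kremCa = k[10]; kdegATP = k[11]; kDiffcAMP = k[12]; kDiffCa = k[13]
    kDiffATP = k[14]; kB = k[15]; kCL = k[16]; k1 = k[17]; k2 = k[18]
    k3 = k[19]; Vpip = k[20]; Vcell = k[21]

    cAMP = y[3]; Ca = y[4]; ATP = y[5]; Res = y[9]; Rel = y[10]

    J = np.zeros((N_STATES, N_STATES))
    stim = EPI + kCL * CL
    vol_ratio = Vcell / Vpip
    mm = Ca / (km + Ca)
    dmm = km / (km + Ca) ** 2          # d(mm)/dCa
    fusion = kcAMP + mm * ATP * kCaATP  # vRel_PM = cAMP * fusion * Rel

    J[0, 0] = -kB * stim
    J[0, 2] = k1
    J[1, 0] = kB * stim
    J[1, 1] = -k2
    J[2, 1] = k2
    J[2, 2] = -k1

    J[3, 1] = k3
    J[3, 3] = -kDiffcAMP * pip - kdegcAMP
    J[3, 6] = kDiffcAMP * pip
    J[4, 4] = -kDiffCa * pip - kremCa
    J[4, 7] = kDiffCa * pip
    J[5, 5] = -kDiffATP * pip - kdegATP
    J[5, 8] = kDiffATP * pip

    J[6, 3] = kDiffcAMP * pip * vol_ratio
    J[6, 6] = -kDiffcAMP * pip * vol_ratio
    J[7, 4] = kDiffCa * pip * vol_ratio
    J[7, 7] = -kDiffCa * pip * vol_ratio
    J[8, 5] = kDiffATP * pip * vol_ratio
    J[8, 8] = -kDiffATP * pip * vol_ratio

    J[10, 3] = -fusion * Rel
    J[10, 4] = dmm * (kCa2 + kATP2 * ATP) * Res - cAMP * dmm * ATP * kCaATP * Rel
    J[10, 5] = mm * kATP2 * Res - cAMP * mm * kCaATP * Rel
    J[10, 9] = mm * (kCa2 + kATP2 * ATP)
    J[10, 10] = -cAMP * fusion
    J[10, 11] = krel
    J[11, 3] = fusion * Rel
    J[11, 4] = cAMP * dmm * ATP * kCaATP * Rel
    J[11, 5] = cAMP * mm * kCaATP * Rel
    J[11, 10] = cAMP * fusion
    J[11, 11] = -krel - kexo

    J[12, 3] = kCacAMP * Ca
    J[12, 4] = kCacAMP * cAMP
    J[12, 12] = -kEndo
    J[13, 11] = kexo
    return J
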