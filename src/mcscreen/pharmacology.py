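"""Binding-assay utilities: Cheng-Prusoff Ki, pKi conversion and
percent-specific-binding normalization.

All concentrations are in nM at the interface; the molar conversion happens
inside :func:`pki`.
"""

from __future__ import annotations

import math

#: displacement thresholds (percent, at the screening concentration)
HIGH_HIT_THRESHOLD = 50.0
MEDIUM_HIT_THRESHOLD = 25.0


def cheng_prusoff_ki(ic50: float, ligand_conc: float, kd: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd), everything in nM.

    ``ligand_conc`` is the radioligand concentration [L] determined per
    experiment; ``kd`` its dissociation constant. ``ligand_conc = 0`` is the
    limit in which Ki equals IC50.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if ligand_conc < 0:
        raise ValueError("ligand_conc must be >= 0")
    return ic50 / (1.0 + ligand_conc / kd)


def pki(ki_nm: float) -> float:
    """pKi = -log10(Ki in molar); input in nM."""
    if ki_nm <= 0:
        raise ValueError("ki must be > 0")
    return -math.log10(ki_nm * 1e-9)


def pki_to_ki(pki_value: float) -> float:
    """Inverse of :func:`pki`: Ki in nM from a pKi."""
    return 10.0 ** (-pki_value) * 1e9


def percent_specific_binding(raw: float, total: float, nonspecific: float) -> float:
    """Normalize counts so total binding reads 100% and nonspecific 0%."""
    if total == nonspecific:
        raise ValueError("total and nonspecific binding must differ")
    return 100.0 * (raw - nonspecific) / (total - nonspecific)


def classify_displacement(
    percent_displacement: float,
    high_threshold: float = HIGH_HIT_THRESHOLD,
    medium_threshold: float = MEDIUM_HIT_THRESHOLD,
) -> str:
    """Bucket a radioligand-displacement percentage into hit categories:
    ``high`` (>= high_threshold), ``medium`` (>= medium_threshold), ``none``."""
    if percent_displacement >= high_threshold:
        return "high"
    if percent_displacement >= medium_threshold:
        return "medium"
    return "none"
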