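"""Synthetic plate-reader optical-density tables.

Emulates a colorimetric assay plate: a twofold-dilution standard series
read through a known (linear or quadratic) concentration-to-OD curve,
plus sample wells at caller-supplied true concentrations, with additive
Gaussian read noise.  The assays module must recover the concentrations
by fitting and inverting the standard curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ground_truth import GroundTruth

__all__ = ["generate_assay_plate"]


def _curve_value(curve_params: dict, conc: np.ndarray) -> np.ndarray:
    kind = curve_params["kind"]
    coeffs = np.asarray(curve_params["coeffs"], dtype=float)
    if kind == "linear":
        a1, a0 = coeffs
        return a1 * conc + a0
    if kind == "quadratic":
        a2, a1, a0 = coeffs
        return a2 * conc**2 + a1 * conc + a0
    raise ValueError(f"unknown curve kind {kind!r}")


def generate_assay_plate(
    true_concentrations,
    curve_params: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
    high_standard: float = 80.0,
    n_standards: int = 9,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an OD table with a standard series and sample wells.

    ``curve_params`` is ``{"kind": "linear"|"quadratic", "coeffs": [...]}``
    with coefficients in descending degree.  The curve must be monotone
    over [0, max concentration] so inversion is well defined.

    Returns a DataFrame with columns (well, role, od) where role is
    'standard', 'sample' or 'blank'; standards descend the twofold
    dilution series from ``high_standard``.
    """
    true_concentrations = np.asarray(true_concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    standards = high_standard / (2.0 ** np.arange(n_standards))
    grid = np.linspace(0, max(high_standard, true_concentrations.max(initial=0.0)), 256)
    ods_grid = _curve_value(curve_params, grid)
    d = np.diff(ods_grid)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("standard curve must be monotone over the concentration range")

    rows = []
    for i, conc in enumerate(standards):
        od = _curve_value(curve_params, np.array([conc]))[0]
        rows.append({"well": f"S{i + 1}", "role": "standard", "od": od})
    rows.append({"well": "B1", "role": "blank", "od": _curve_value(curve_params, np.array([0.0]))[0]})
    for i, conc in enumerate(true_concentrations):
        od = _curve_value(curve_params, np.array([conc]))[0]
        rows.append({"well": f"X{i + 1}", "role": "sample", "od": od})
    table = pd.DataFrame(rows)
    if noise_sd > 0:
        table["od"] = table["od"] + rng.normal(0, noise_sd, len(table))

    truth = GroundTruth(
        "plate",
        {
            "standards": standards,
            "standard_ods_clean": _curve_value(curve_params, standards),
            "true_concentrations": true_concentrations,
            "curve_params": {"kind": curve_params["kind"], "coeffs": list(curve_params["coeffs"])},
            "noise_sd": noise_sd,
        },
    )
    return table, truth
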