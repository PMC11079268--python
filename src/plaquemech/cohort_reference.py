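"""Published per-patient wall stress/strain summaries of the 10-patient study.

These are the reported per-case maximum and mean values of the maximum
principal stress (kPa) and strain on the vessel inner wall and out-wall,
for the four model variants (multi-/single-layer, with/without residual
stress), together with the reported per-case percent ratios
(100 x with / without).  The percent ratios were published computed from
unrounded values, so they are carried alongside the rounded absolute values
rather than recomputed.  They serve as the reference input for validating
the cohort aggregation arithmetic (Mean +/- STD rows and the headline
reduction/increase percentages).
"""

from __future__ import annotations

from .pipeline import ComparisonRow

_PATIENTS = [f"P{i}" for i in range(1, 11)]

# (quantity, variant) -> ten per-patient values, patient order P1..P10
VALUES = {
    # ---- inner wall, maximum principal stress (kPa), maxima
    ("inner_stress_max", "multi", True): [
        124.74, 60.54, 176.22, 178.66, 101.76, 293.74, 289.90, 109.26, 47.06, 103.46],
    ("inner_stress_max", "multi", False): [
        238.71, 126.87, 195.62, 346.11, 249.30, 260.33, 388.15, 334.76, 124.67, 140.02],
    ("inner_stress_max", "single", True): [
        57.96, 6.34, 72.97, 29.35, 67.26, 96.29, 158.10, 49.61, 45.79, 7.80],
    ("inner_stress_max", "single", False): [
        146.95, 65.94, 143.34, 214.84, 129.92, 141.88, 204.86, 209.43, 103.49, 111.01],
    # ---- inner wall, means
    ("inner_stress_mean", "multi", True): [
        42.89, 26.52, 33.19, 58.69, 37.29, 111.33, 107.47, 44.93, -0.54, 45.06],
    ("inner_stress_mean", "multi", False): [
        109.61, 71.94, 99.16, 159.02, 120.55, 138.60, 203.26, 99.93, 38.72, 92.10],
    ("inner_stress_mean", "single", True): [
        1.29, -3.85, -11.56, 3.29, 4.02, 37.03, 34.75, 11.85, -3.25, -4.69],
    ("inner_stress_mean", "single", False): [
        70.81, 47.59, 65.54, 85.64, 79.93, 94.36, 124.70, 71.71, 34.47, 73.13],
    # ---- inner wall, strain maxima
    ("inner_strain_max", "multi", True): [
        0.194, 0.097, 0.155, 0.141, 0.204, 0.199, 0.203, 0.118, 0.148, 0.125],
    ("inner_strain_max", "multi", False): [
        0.308, 0.256, 0.214, 0.353, 0.197, 0.287, 0.217, 0.180, 0.189, 0.222],
    ("inner_strain_max", "single", True): [
        0.130, 0.094, 0.186, 0.108, 0.164, 0.149, 0.171, 0.074, 0.214, 0.054],
    ("inner_strain_max", "single", False): [
        0.282, 0.242, 0.177, 0.284, 0.170, 0.269, 0.197, 0.155, 0.184, 0.207],
    # ---- inner wall, strain means
    ("inner_strain_mean", "multi", True): [
        0.062, 0.032, 0.069, 0.079, 0.066, 0.090, 0.102, 0.064, 0.034, 0.053],
    ("inner_strain_mean", "multi", False): [
        0.161, 0.137, 0.119, 0.146, 0.128, 0.144, 0.158, 0.117, 0.109, 0.156],
    ("inner_strain_mean", "single", True): [
        0.024, 0.029, 0.061, 0.052, 0.059, 0.061, 0.067, 0.053, 0.067, 0.014],
    ("inner_strain_mean", "single", False): [
        0.140, 0.119, 0.099, 0.112, 0.106, 0.123, 0.130, 0.100, 0.105, 0.144],
    # ---- out-wall, stress maxima
    ("outer_stress_max", "multi", True): [
        165.49, 209.17, 246.51, 231.92, 114.51, 199.11, 233.05, 164.42, 391.54, 155.81],
    ("outer_stress_max", "multi", False): [
        48.88, 24.49, 25.66, 46.17, 35.07, 44.76, 46.68, 32.12, 24.99, 21.54],
    ("outer_stress_max", "single", True): [
        345.65, 305.38, 358.05, 271.38, 516.57, 294.56, 364.80, 265.36, 780.87, 500.19],
    ("outer_stress_max", "single", False): [
        75.42, 36.51, 42.23, 72.96, 64.67, 80.32, 90.51, 57.63, 28.08, 36.12],
    # ---- out-wall, stress means
    ("outer_stress_mean", "multi", True): [
        89.30, 99.72, 96.99, 102.69, 60.00, 84.22, 91.82, 80.48, 153.02, 112.05],
    ("outer_stress_mean", "multi", False): [
        24.85, 16.79, 16.58, 29.81, 20.68, 22.83, 29.16, 19.80, 10.90, 17.15],
    ("outer_stress_mean", "single", True): [
        185.90, 183.28, 163.43, 149.97, 220.26, 154.52, 168.47, 146.60, 327.86, 245.26],
    ("outer_stress_mean", "single", False): [
        41.01, 24.90, 25.38, 48.19, 35.55, 38.71, 53.02, 32.70, 15.32, 29.09],
    # ---- out-wall, strain maxima
    ("outer_strain_max", "multi", True): [
        0.358, 0.389, 0.396, 0.397, 0.435, 0.326, 0.306, 0.307, 0.451, 0.326],
    ("outer_strain_max", "multi", False): [
        0.194, 0.099, 0.073, 0.148, 0.097, 0.130, 0.141, 0.098, 0.110, 0.088],
    ("outer_strain_max", "single", True): [
        0.266, 0.275, 0.258, 0.279, 0.303, 0.229, 0.218, 0.213, 0.371, 0.244],
    ("outer_strain_max", "single", False): [
        0.120, 0.078, 0.059, 0.083, 0.081, 0.099, 0.109, 0.073, 0.065, 0.073],
    # ---- out-wall, strain means
    ("outer_strain_mean", "multi", True): [
        0.246, 0.248, 0.227, 0.238, 0.171, 0.200, 0.205, 0.194, 0.245, 0.271],
    ("outer_strain_mean", "multi", False): [
        0.087, 0.049, 0.055, 0.082, 0.065, 0.070, 0.086, 0.062, 0.026, 0.058],
    ("outer_strain_mean", "single", True): [
        0.176, 0.189, 0.161, 0.151, 0.114, 0.154, 0.152, 0.146, 0.209, 0.193],
    ("outer_strain_mean", "single", False): [
        0.072, 0.039, 0.051, 0.058, 0.056, 0.061, 0.067, 0.055, 0.020, 0.053],
}

# (quantity, layers) -> published per-patient percent ratios (with/without)
RATIOS = {
    ("inner_stress_max", "multi"): [
        52.26, 47.72, 90.08, 51.62, 40.82, 112.83, 74.69, 32.64, 37.75, 73.88],
    ("inner_stress_max", "single"): [
        39.44, 9.62, 50.91, 13.66, 51.77, 67.87, 77.17, 23.69, 44.24, 7.03],
    ("inner_stress_mean", "multi"): [
        39.13, 36.87, 33.47, 36.91, 30.93, 80.33, 52.87, 44.96, -1.40, 48.92],
    ("inner_stress_mean", "single"): [
        1.83, -8.09, -17.65, 3.84, 5.03, 39.24, 27.87, 16.53, -9.44, -6.41],
    ("inner_strain_max", "multi"): [
        63.00, 38.06, 72.44, 39.85, 103.89, 69.40, 93.39, 65.60, 78.58, 56.20],
    ("inner_strain_max", "single"): [
        46.06, 39.02, 105.39, 37.98, 96.49, 55.38, 86.81, 47.63, 116.52, 25.99],
    ("inner_strain_mean", "multi"): [
        38.40, 23.02, 57.77, 54.10, 51.71, 62.41, 64.87, 54.53, 31.20, 33.63],
    ("inner_strain_mean", "single"): [
        17.29, 24.14, 62.21, 46.85, 55.30, 49.85, 51.23, 52.33, 64.11, 9.86],
    ("outer_stress_max", "multi"): [
        338.56, 854.16, 960.49, 502.30, 326.54, 444.89, 499.21, 511.84, 1567.07, 723.35],
    ("outer_stress_max", "single"): [
        458.33, 836.33, 847.82, 371.95, 798.82, 366.73, 403.04, 460.45, 2781.11, 1384.68],
    ("outer_stress_mean", "multi"): [
        359.34, 594.04, 584.91, 344.51, 290.13, 368.89, 314.89, 406.48, 1403.62, 653.45],
    ("outer_stress_mean", "single"): [
        453.29, 736.21, 643.83, 311.21, 619.59, 399.20, 317.76, 448.32, 2140.55, 843.18],
    ("outer_strain_max", "multi"): [
        185.02, 394.26, 545.80, 267.60, 450.40, 250.78, 216.83, 313.53, 409.14, 368.79],
    ("outer_strain_max", "single"): [
        221.29, 353.28, 439.17, 334.96, 374.63, 231.07, 200.96, 293.67, 572.17, 333.85],
    ("outer_strain_mean", "multi"): [
        284.02, 501.91, 411.36, 288.94, 262.11, 286.78, 237.90, 313.06, 943.74, 468.03],
    ("outer_strain_mean", "single"): [
        244.89, 479.25, 312.73, 260.47, 205.59, 251.55, 227.53, 266.24, 1038.05, 362.55],
}


def reference_rows() -> list:
    """The published per-patient summaries as :class:`ComparisonRow` objects."""
    rows = []
    for i, pid in enumerate(_PATIENTS):
        values = {}
        for (q, layers, residual), series in _by_variant().items():
            values.setdefault((layers, residual), {})[q] = series[i]
        ratios = {(layers, q): RATIOS[(q, layers)][i] for (q, layers) in RATIOS}
        rows.append(ComparisonRow.from_values(pid, values, ratios))
    return rows


def _by_variant() -> dict:
    return {(q, layers, residual): vals
            for (q, layers, residual), vals in VALUES.items()}
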