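"""Bundled per-edge reference measurements.

A table of ciliary beat parameters and fitted velocity-profile parameters
for 24 ciliated edges from nasal brushings of 11 subjects: beat frequency
(CBF, Hz), beat amplitude (CBA, μm), metachronal wavelength (λ, μm), cilia
density (ρc, fraction), the fitted stagnant-fluid altitude h (μm), the
extrapolated wall velocity Uw* (μm/s), and the published shear-stress
index τw (mPa).

One edge (subject 2, first edge) carries a τw inconsistent with its own
(h, Uw*) pair — an apparent typo in h — and is flagged
``tau_consistent = False`` so analyses can quarantine it.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # patient, edge, n_beads, cbf, cba, lam, rho%, h, uw, tau, consistent
    (1, 1, 8, 14.0, 7.5, 13.0, 84, 87.5, 138.3, 3.2, True),
    (1, 2, 4, 15.0, 6.8, 14.6, 86, 52.6, 240.9, 9.2, True),
    (1, 3, 5, 13.5, 7.5, 19.8, 89, 47.4, 224.8, 9.5, True),
    (1, 4, 5, 13.6, 4.0, 28.0, 82, 70.9, 49.4, 1.4, True),
    (2, 1, 3, 5.3, 7.0, 10.8, 73, 7.0, 27.6, 0.7, False),
    (2, 2, 3, 5.6, 6.6, 11.3, 80, 32.9, 46.9, 2.9, True),
    (2, 3, 9, 6.3, 7.3, 11.0, 68, 28.9, 55.2, 3.8, True),
    (3, 1, 6, 14.0, 5.4, 10.5, 69, 53.0, 51.3, 1.9, True),
    (4, 1, 4, 11.5, 7.5, 12.0, 74, 66.3, 76.8, 2.3, True),
    (5, 1, 3, 7.3, 7.8, 16.0, 58, 82.1, 24.0, 0.6, True),
    (5, 2, 3, 9.4, 7.0, 15.5, 80, 91.5, 80.1, 1.8, True),
    (5, 3, 3, 4.9, 8.4, 17.3, 88, 53.5, 64.7, 2.4, True),
    (5, 4, 4, 5.6, 6.9, 13.3, 95, 52.8, 106.5, 4.0, True),
    (5, 5, 3, 8.1, 6.7, 15.4, 82, 139.7, 85.4, 1.2, True),
    (6, 1, 4, 3.7, 6.2, 16.7, 89, 34.2, 33.6, 2.0, True),
    (7, 1, 4, 7.7, 7.2, 12.0, 70, 42.6, 49.3, 2.3, True),
    (8, 1, 3, 3.6, 6.3, 17.7, 98, 40.1, 32.3, 1.6, True),
    (9, 1, 12, 7.7, 8.8, 12.1, 62, 60.0, 51.7, 1.7, True),
    (9, 2, 5, 6.6, 7.0, 10.3, 73, 52.3, 54.4, 2.1, True),
    (10, 1, 3, 6.7, 6.5, 10.4, 87, 28.6, 60.2, 4.2, True),
    (11, 1, 56, 3.6, 4.7, 10.2, 96, 51.2, 58.9, 2.3, True),
    (11, 2, 11, 3.5, 5.3, 12.6, 89, 48.6, 45.6, 1.9, True),
    (11, 3, 6, 4.9, 4.8, 18.5, 89, 50.5, 44.3, 1.8, True),
    (11, 4, 28, 6.0, 5.2, 16.7, 86, 45.4, 56.4, 2.5, True),
]

_PUBLISHED_SUMMARY = {
    # patient -> (mean tau, sample SD or None) as published
    1: (5.8, 4.1), 2: (2.5, 1.6), 3: (1.9, None), 4: (2.3, None),
    5: (2.0, 1.3), 6: (2.0, None), 7: (2.3, None), 8: (1.6, None),
    9: (1.9, 0.3), 10: (4.2, None), 11: (2.1, 0.3),
}


def edge_measurements() -> pd.DataFrame:
    """The per-edge reference table as a DataFrame (ρc as fraction)."""
    df = pd.DataFrame(_ROWS, columns=[
        "patient", "edge", "n_beads", "cbf_hz", "cba_um", "wavelength_um",
        "rho_c_pct", "h_um", "uw_um_s", "tau_mpa", "tau_consistent"])
    df["rho_c"] = df["rho_c_pct"] / 100.0
    return df


def published_patient_summary() -> dict:
    """Published per-patient mean ± sample SD of τw (SD None if one edge)."""
    return dict(_PUBLISHED_SUMMARY)
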