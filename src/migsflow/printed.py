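"""Published reference grid of postoperative IOPs (transcribed once, by hand).

Each row is (device, p_g, p_b, p_c, efficacy, cfd_noise): pressures in mmHg,
efficacy in percent (None where the source prints a dash because the scarred
bleb drives the IOP above baseline).  ``cfd_noise`` marks cells where the
published 3D-simulation value departs from the lumped analytical model by
more than 0.5 mmHg; these are concentrated at low bleb pressures in the
p_g = 25 and 50 mmHg blocks and are excluded from regression comparisons.
"""

from __future__ import annotations

from typing import List, NamedTuple, Optional


class PrintedCell(NamedTuple):
    device: str
    p_g: float
    p_b: float
    p_c: float
    efficacy: Optional[int]
    cfd_noise: bool


REFERENCE_CELLS: List[PrintedCell] = [
    PrintedCell("XEN 45-6mm", 25, 0, 12.2, 51, True),
    PrintedCell("XEN 45-6mm", 25, 5, 14.8, 40, True),
    PrintedCell("XEN 45-6mm", 25, 10, 17.6, 29, True),
    PrintedCell("XEN 45-6mm", 25, 17, 20.1, 19, False),
    PrintedCell("XEN 45-6mm", 25, 20, 22.4, 10, True),
    PrintedCell("XEN 45-6mm", 25, 34, 30.4, None, False),
    PrintedCell("XEN 45-6mm", 30, 2, 11.1, 63, False),
    PrintedCell("XEN 45-6mm", 30, 5, 13.1, 56, False),
    PrintedCell("XEN 45-6mm", 30, 10, 16.52, 44, False),
    PrintedCell("XEN 45-6mm", 30, 17, 21.2, 29, False),
    PrintedCell("XEN 45-6mm", 30, 20, 23.2, 22, False),
    PrintedCell("XEN 45-6mm", 30, 34, 32.6, None, False),
    PrintedCell("XEN 45-6mm", 50, 0, 13.06, 73, True),
    PrintedCell("XEN 45-6mm", 50, 5, 16.7, 66, True),
    PrintedCell("XEN 45-6mm", 50, 10, 20.4, 59, True),
    PrintedCell("XEN 45-6mm", 50, 17, 23.3, 53, False),
    PrintedCell("XEN 45-6mm", 50, 20, 27.8, 44, True),
    PrintedCell("XEN 45-6mm", 50, 34, 37.1, 25, False),
    PrintedCell("XEN 45-5mm", 25, 0, 11.1, 55, True),
    PrintedCell("XEN 45-5mm", 25, 5, 13.9, 44, True),
    PrintedCell("XEN 45-5mm", 25, 10, 16.6, 33, True),
    PrintedCell("XEN 45-5mm", 25, 17, 19.8, 20, False),
    PrintedCell("XEN 45-5mm", 25, 20, 22.2, 11, True),
    PrintedCell("XEN 45-5mm", 25, 34, 30.8, None, False),
    PrintedCell("XEN 45-5mm", 30, 2, 10.0, 66, False),
    PrintedCell("XEN 45-5mm", 30, 5, 12.2, 59, False),
    PrintedCell("XEN 45-5mm", 30, 10, 15.7, 47, False),
    PrintedCell("XEN 45-5mm", 30, 17, 20.7, 31, False),
    PrintedCell("XEN 45-5mm", 30, 20, 22.8, 24, False),
    PrintedCell("XEN 45-5mm", 30, 34, 32.8, None, False),
    PrintedCell("XEN 45-5mm", 50, 0, 11.3, 77, True),
    PrintedCell("XEN 45-5mm", 50, 5, 15.2, 69, True),
    PrintedCell("XEN 45-5mm", 50, 10, 19.1, 61, True),
    PrintedCell("XEN 45-5mm", 50, 17, 22.5, 55, False),
    PrintedCell("XEN 45-5mm", 50, 20, 26.8, 46, True),
    PrintedCell("XEN 45-5mm", 50, 34, 36.6, 26, False),
    PrintedCell("XEN 63-6mm", 25, 0, 5.0, 80, True),
    PrintedCell("XEN 63-6mm", 25, 5, 9.0, 64, True),
    PrintedCell("XEN 63-6mm", 25, 10, 13.0, 48, True),
    PrintedCell("XEN 63-6mm", 25, 17, 18.1, 18, False),
    PrintedCell("XEN 63-6mm", 25, 20, 21.0, 16, False),
    PrintedCell("XEN 63-6mm", 25, 34, 32.6, None, False),
    PrintedCell("XEN 63-6mm", 30, 2, 5.1, 83, False),
    PrintedCell("XEN 63-6mm", 30, 5, 7.8, 74, False),
    PrintedCell("XEN 63-6mm", 30, 10, 12.2, 59, False),
    PrintedCell("XEN 63-6mm", 30, 17, 18.4, 38, False),
    PrintedCell("XEN 63-6mm", 30, 20, 21.2, 29, False),
    PrintedCell("XEN 63-6mm", 30, 34, 33.5, None, False),
    PrintedCell("XEN 63-6mm", 50, 0, 4.2, 91, True),
    PrintedCell("XEN 63-6mm", 50, 5, 8.7, 82, True),
    PrintedCell("XEN 63-6mm", 50, 10, 13.3, 73, True),
    PrintedCell("XEN 63-6mm", 50, 17, 18.9, 62, False),
    PrintedCell("XEN 63-6mm", 50, 20, 22.5, 55, True),
    PrintedCell("XEN 63-6mm", 50, 34, 34.9, 30, False),
    PrintedCell("XEN 63-5mm", 25, 0, 4.3, 82, True),
    PrintedCell("XEN 63-5mm", 25, 5, 8.4, 66, True),
    PrintedCell("XEN 63-5mm", 25, 10, 12.5, 50, True),
    PrintedCell("XEN 63-5mm", 25, 17, 17.9, 17, False),
    PrintedCell("XEN 63-5mm", 25, 20, 20.8, 16, False),
    PrintedCell("XEN 63-5mm", 25, 34, 32.8, None, False),
    PrintedCell("XEN 63-5mm", 30, 2, 4.6, 84, False),
    PrintedCell("XEN 63-5mm", 30, 5, 7.3, 75, False),
    PrintedCell("XEN 63-5mm", 30, 10, 11.9, 60, False),
    PrintedCell("XEN 63-5mm", 30, 17, 18.2, 39, False),
    PrintedCell("XEN 63-5mm", 30, 20, 20.9, 30, False),
    PrintedCell("XEN 63-5mm", 30, 34, 33.6, None, False),
    PrintedCell("XEN 63-5mm", 50, 0, 3.5, 93, True),
    PrintedCell("XEN 63-5mm", 50, 5, 8.2, 83, True),
    PrintedCell("XEN 63-5mm", 50, 10, 12.8, 74, True),
    PrintedCell("XEN 63-5mm", 50, 17, 18.6, 62, False),
    PrintedCell("XEN 63-5mm", 50, 20, 22.1, 55, True),
    PrintedCell("XEN 63-5mm", 50, 34, 34.7, 30, False),
    PrintedCell("PreserFlo-8.5mm", 25, 0, 4.7, 81, True),
    PrintedCell("PreserFlo-8.5mm", 25, 5, 8.7, 65, True),
    PrintedCell("PreserFlo-8.5mm", 25, 10, 12.8, 48, True),
    PrintedCell("PreserFlo-8.5mm", 25, 17, 18.0, 18, False),
    PrintedCell("PreserFlo-8.5mm", 25, 20, 20.9, 16, False),
    PrintedCell("PreserFlo-8.5mm", 25, 34, 32.7, None, False),
    PrintedCell("PreserFlo-8.5mm", 30, 2, 4.9, 83, False),
    PrintedCell("PreserFlo-8.5mm", 30, 5, 7.6, 74, False),
    PrintedCell("PreserFlo-8.5mm", 30, 10, 12.1, 59, False),
    PrintedCell("PreserFlo-8.5mm", 30, 17, 18.3, 39, False),
    PrintedCell("PreserFlo-8.5mm", 30, 20, 21.0, 30, False),
    PrintedCell("PreserFlo-8.5mm", 30, 34, 33.5, None, False),
    PrintedCell("PreserFlo-8.5mm", 50, 0, 3.9, 92, True),
    PrintedCell("PreserFlo-8.5mm", 50, 5, 8.5, 83, True),
    PrintedCell("PreserFlo-8.5mm", 50, 10, 13.1, 73, True),
    PrintedCell("PreserFlo-8.5mm", 50, 17, 18.8, 62, False),
    PrintedCell("PreserFlo-8.5mm", 50, 20, 22.3, 55, True),
    PrintedCell("PreserFlo-8.5mm", 50, 34, 34.8, 30, False),
    PrintedCell("PreserFlo-7.5mm", 25, 0, 4.2, 83, True),
    PrintedCell("PreserFlo-7.5mm", 25, 5, 8.4, 66, True),
    PrintedCell("PreserFlo-7.5mm", 25, 10, 12.5, 50, True),
    PrintedCell("PreserFlo-7.5mm", 25, 17, 17.9, 17, False),
    PrintedCell("PreserFlo-7.5mm", 25, 20, 20.5, 18, False),
    PrintedCell("PreserFlo-7.5mm", 25, 34, 32.8, None, False),
    PrintedCell("PreserFlo-7.5mm", 30, 2, 4.6, 83, False),
    PrintedCell("PreserFlo-7.5mm", 30, 5, 7.3, 74, False),
    PrintedCell("PreserFlo-7.5mm", 30, 10, 11.8, 59, False),
    PrintedCell("PreserFlo-7.5mm", 30, 17, 18.2, 39, False),
    PrintedCell("PreserFlo-7.5mm", 30, 20, 20.9, 30, False),
    PrintedCell("PreserFlo-7.5mm", 30, 34, 33.6, None, False),
    PrintedCell("PreserFlo-7.5mm", 50, 0, 3.5, 93, True),
    PrintedCell("PreserFlo-7.5mm", 50, 5, 8.1, 83, True),
    PrintedCell("PreserFlo-7.5mm", 50, 10, 12.8, 74, True),
    PrintedCell("PreserFlo-7.5mm", 50, 17, 18.6, 62, False),
    PrintedCell("PreserFlo-7.5mm", 50, 20, 22.1, 55, True),
    PrintedCell("PreserFlo-7.5mm", 50, 34, 34.7, 30, False),
]


def concordant_cells() -> List[PrintedCell]:
    """Cells where published CFD and the analytical model agree (no noise flag)."""
    return [c for c in REFERENCE_CELLS if not c.cfd_noise]
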