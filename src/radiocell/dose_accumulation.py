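"""MIRD-scheme dose accumulation: S values x time-integrated activities.

Absorbed dose to the nucleus is accumulated over two phases of the
clonogenic assay:

* **incubation** (3 h, cells in suspension — floating spherical S values):
  cell-bound activity held constant apart from physical decay, split
  between membrane and cytoplasm by the constant partition; the medium
  carries 100% of the added activity (1 mL), and for the beta emitter a
  cross-dose term from neighbouring suspension cells is added;
* **colony growth** (7 d, cells attached — ellipsoidal S values):
  cell-bound activity follows physical decay times the biological
  clearance (exponential to a plateau); medium and cross terms are absent
  (medium removed, colonies far apart).

Total dose is the sum of components; everything is linear in the added
activity concentration at fixed kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from radiocell.kinetics import (
    ClearanceModel,
    PartitionModel,
    bound_activity_per_cell,
    time_integrated_activity,
)
from radiocell.nuclide_data import HOUR, half_life_s
from radiocell.svalue_engine import SValueTable

__all__ = [
    "AssayProtocol",
    "DoseBreakdown",
    "phase_dose",
    "dose_table",
    "DEFAULT_PROTOCOL",
]


@dataclass(frozen=True)
class AssayProtocol:
    """Exposure protocol of the clonogenic assay."""

    incubation_h: float = 3.0
    colony_growth_h: float = 168.0  # dose cumulated up to 7 days
    volume_ml: float = 1.0
    n_cells: float = 1e5
    uptake_pct_per_1e5_cells: float = 1.865  # mean of the 1 h and 3 h uptake
    medium_mass_g: float = 1.0


DEFAULT_PROTOCOL = AssayProtocol()

DEFAULT_CLEARANCE = ClearanceModel(plateau_fraction=0.41, biological_half_life_h=2.3)


@dataclass(frozen=True)
class DoseBreakdown:
    """Absorbed dose (Gy) to the nucleus, by source component."""

    nuclide: str
    concentration_bq_per_ml: float
    size_class: str
    self_membrane_gy: float
    self_cytoplasm_gy: float
    cross_gy: float
    medium_gy: float
    excluded_from_fit: bool = False

    @property
    def total_gy(self) -> float:
        return (
            self.self_membrane_gy
            + self.self_cytoplasm_gy
            + self.cross_gy
            + self.medium_gy
        )


def phase_dose(
    nuclide: str,
    concentration_bq_per_ml: float,
    svalues: SValueTable,
    size_class: str = "average",
    partition: PartitionModel | None = None,
    clearance: ClearanceModel | None = None,
    protocol: AssayProtocol = DEFAULT_PROTOCOL,
) -> DoseBreakdown:
    """Dose components (Gy) for one nuclide/concentration/size class.

    Incubation uses floating (spherical) S values, colony growth attached
    (ellipsoidal) ones; the geometry switch is instantaneous at the end of
    incubation.  The cross term is taken from the S-value table (zero for
    the alpha emitter), applied during incubation only.
    """
    partition = partition or PartitionModel()
    clearance = clearance or DEFAULT_CLEARANCE
    if concentration_bq_per_ml < 0:
        raise ValueError("concentration must be >= 0")

    t_phys_h = half_life_s(nuclide) / HOUR
    a_cell = bound_activity_per_cell(
        concentration_bq_per_ml,
        protocol.volume_ml,
        protocol.uptake_pct_per_1e5_cells,
        protocol.n_cells,
    )

    # --- incubation (floating) --------------------------------------------
    tia_inc = time_integrated_activity(a_cell, t_phys_h, None, protocol.incubation_h)
    s_mem_f = svalues.self_svalue(nuclide, "cell_membrane", "floating", size_class)
    s_cyt_f = svalues.self_svalue(nuclide, "cytoplasm", "floating", size_class)
    d_mem = tia_inc * partition.membrane_fraction * s_mem_f
    d_cyt = tia_inc * partition.internal_fraction * s_cyt_f
    d_cross = tia_inc * svalues.cross_svalue(nuclide)

    added_bq = concentration_bq_per_ml * protocol.volume_ml
    tia_medium = time_integrated_activity(
        added_bq, t_phys_h, None, protocol.incubation_h
    )
    d_medium = tia_medium * svalues.medium_svalue(nuclide)

    # --- colony growth (attached) -----------------------------------------
    a_start = a_cell * _decay_factor(t_phys_h, protocol.incubation_h)
    tia_col = time_integrated_activity(
        a_start, t_phys_h, clearance, protocol.colony_growth_h
    )
    s_mem_a = svalues.self_svalue(nuclide, "cell_membrane", "attached", size_class)
    s_cyt_a = svalues.self_svalue(nuclide, "cytoplasm", "attached", size_class)
    d_mem += tia_col * partition.membrane_fraction * s_mem_a
    d_cyt += tia_col * partition.internal_fraction * s_cyt_a

    return DoseBreakdown(
        nuclide=nuclide,
        concentration_bq_per_ml=concentration_bq_per_ml,
        size_class=size_class,
        self_membrane_gy=d_mem,
        self_cytoplasm_gy=d_cyt,
        cross_gy=d_cross,
        medium_gy=d_medium,
    )


def _decay_factor(half_life_h: float, t_h: float) -> float:
    return math.exp(-math.log(2.0) * t_h / half_life_h)


def dose_table(
    nuclide: str,
    concentrations_bq_per_ml: list[float],
    svalues: SValueTable,
    partition: PartitionModel | None = None,
    clearance: ClearanceModel | None = None,
    protocol: AssayProtocol = DEFAULT_PROTOCOL,
    size_classes: tuple[str, ...] = ("average", "minimum", "maximum"),
    exclude_above_bq_per_ml: float | None = None,
) -> pd.DataFrame:
    """Cumulated 7-day dose table: one row per concentration x size class.

    ``exclude_above_bq_per_ml`` flags rows whose concentration exceeds the
    threshold as excluded from dose-response fitting (the highest activity
    concentrations are left out of the correlation).
    """
    rows = []
    for conc in concentrations_bq_per_ml:
        for size in size_classes:
            bd = phase_dose(
                nuclide, conc, svalues,
                size_class=size, partition=partition,
                clearance=clearance, protocol=protocol,
            )
            rows.append(
                {
                    "nuclide": nuclide,
                    "concentration_bq_per_ml": conc,
                    "size_class": size,
                    "self_membrane_gy": bd.self_membrane_gy,
                    "self_cytoplasm_gy": bd.self_cytoplasm_gy,
                    "cross_gy": bd.cross_gy,
                    "medium_gy": bd.medium_gy,
                    "total_gy": bd.total_gy,
                    "excluded_from_fit": (
                        exclude_above_bq_per_ml is not None
                        and conc > exclude_above_bq_per_ml
                    ),
                }
            )
    return pd.DataFrame(rows)
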