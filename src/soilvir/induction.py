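"""Quantification of viral/bacterial enumeration and mitomycin-C induction assays.

A prophage induction assay yields four epifluorescence counts: viral and
bacterial abundance in an un-induced control tube (``Vc``, ``Bc``) and in a
mitomycin-C treated tube (``Vm``, ``Bm``), all per gram of soil.  From these
the module derives

* burst size ``BZ = (Vm - Vc) / (Bc - Bm)`` — viruses released per lysed cell,
* the inducible fraction ``IF = 100 * [(Vm - Vc) / BZ] / Bc`` (which reduces
  algebraically to ``100 * (Bc - Bm) / Bc`` when the calculated burst size is
  used),
* the inducible fraction under an assumed burst size (default 20 viruses per
  cell), ``IF20 = 100 * [(Vm - Vc) / 20] / Bc``,
* the percent increase in viral abundance, ``100 * (Vm - Vc) / Vc``,

plus the virus-to-bacteria ratio (VBR) for plain enumeration records.

Degenerate assays are flagged rather than raised: when growth of the
non-induced bacteria outpaces lysis (``Bm >= Bc``) the calculated burst size
is undefined (``growth_dominated``); when ``Vm <= Vc`` there is no induction
signal (``no_induction``); a defined burst size below one virus per lysed
cell is biologically unreasonable and flagged ``low_burst``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ASSUMED_BURST_SIZE = 20.0

#: QC flag names attached to induction results.
FLAG_NO_INDUCTION = "no_induction"
FLAG_GROWTH_DOMINATED = "growth_dominated"
FLAG_LOW_BURST = "low_burst"


class UndefinedRatioError(ValueError):
    """Raised when a ratio's denominator is zero."""


@dataclass(frozen=True)
class InductionAssay:
    """The four counts a mitomycin-C induction experiment yields.

    Attributes
    ----------
    vc, vm:
        Viral counts (VLP g^-1) in the control and mitC-treated tube.
    bc, bm:
        Bacterial counts (cells g^-1) in the control and mitC-treated tube,
        both measured after the overnight incubation.
    """

    vc: float
    vm: float
    bc: float
    bm: float

    def __post_init__(self) -> None:
        for name in ("vc", "vm", "bc", "bm"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite non-negative count, got {value!r}")


@dataclass(frozen=True)
class InductionResult:
    """Derived statistics for one induction assay."""

    delta_v: float
    bz_calc: float | None
    if_calc: float | None
    if_assumed: float
    pct_increase: float | None
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class AbundanceRecord:
    """Viral and bacterial abundance of one sample plus their ratio."""

    viral_abundance: float
    bacterial_abundance: float

    @property
    def vbr(self) -> float:
        return virus_bacteria_ratio(self.viral_abundance, self.bacterial_abundance)


def virus_bacteria_ratio(va: float, ba: float) -> float:
    """Virus-to-bacteria ratio VBR = VA / BA.

    Parameters
    ----------
    va : viral abundance, VLP g^-1.
    ba : bacterial abundance, cells g^-1; must be positive.
    """
    if ba <= 0:
        raise UndefinedRatioError(f"VBR undefined for bacterial abundance {ba!r}")
    return va / ba


def estimate_burst_size(assay: InductionAssay) -> tuple[float | None, frozenset[str]]:
    """Calculated burst size BZ = (Vm - Vc) / (Bc - Bm) with QC flags.

    Returns ``(None, flags)`` when the estimate is undefined: ``Bm >= Bc``
    (growth dominated the incubation) or ``Vm <= Vc`` (no induction signal).
    A defined estimate below 1 virus per lysed cell carries ``low_burst``.
    """
    flags: set[str] = set()
    delta_v = assay.vm - assay.vc
    delta_b = assay.bc - assay.bm
    if delta_v <= 0:
        flags.add(FLAG_NO_INDUCTION)
    if delta_b <= 0:
        flags.add(FLAG_GROWTH_DOMINATED)
    if flags:
        return None, frozenset(flags)
    bz = delta_v / delta_b
    if bz < 1.0:
        flags.add(FLAG_LOW_BURST)
    return bz, frozenset(flags)


def inducible_fraction_calculated(assay: InductionAssay) -> tuple[float | None, frozenset[str]]:
    """Inducible fraction using the calculated burst size, in percent.

    ``IF = 100 * [(Vm - Vc) / BZ] / Bc`` which, with ``BZ = dV/dB``, is
    algebraically ``100 * (Bc - Bm) / Bc``.  Undefined (with the burst-size
    flags) whenever the calculated burst size is undefined.
    """
    if assay.bc <= 0:
        raise UndefinedRatioError("IF undefined: control bacterial count is zero")
    bz, flags = estimate_burst_size(assay)
    if bz is None:
        return None, flags
    value = 100.0 * ((assay.vm - assay.vc) / bz) / assay.bc
    return value, flags


def inducible_fraction_assumed(
    assay: InductionAssay, assumed_bz: float = DEFAULT_ASSUMED_BURST_SIZE
) -> tuple[float, frozenset[str]]:
    """Inducible fraction under an assumed burst size (default 20), in percent.

    ``IF = 100 * [(Vm - Vc) / assumed_bz] / Bc``.  A negative viral response
    yields a negative value carrying ``no_induction`` — negative statistics
    are reported, not clipped, since they are a QC signal.
    """
    if assumed_bz <= 0:
        raise ValueError(f"assumed burst size must be positive, got {assumed_bz!r}")
    if assay.bc <= 0:
        raise UndefinedRatioError("IF undefined: control bacterial count is zero")
    delta_v = assay.vm - assay.vc
    flags = frozenset({FLAG_NO_INDUCTION}) if delta_v <= 0 else frozenset()
    return 100.0 * (delta_v / assumed_bz) / assay.bc, flags


def percent_induction_increase(assay: InductionAssay) -> tuple[float, frozenset[str]]:
    """Percent increase in viral abundance of induced over control samples.

    ``100 * (Vm - Vc) / Vc``; requires a positive control count.
    """
    if assay.vc <= 0:
        raise UndefinedRatioError("percent increase undefined: control viral count is zero")
    value = 100.0 * (assay.vm - assay.vc) / assay.vc
    flags = frozenset({FLAG_NO_INDUCTION}) if value < 0 else frozenset()
    return value, flags


def analyze_assay(
    assay: InductionAssay, assumed_bz: float = DEFAULT_ASSUMED_BURST_SIZE
) -> InductionResult:
    """All induction statistics for a single assay, with merged flags."""
    bz, bz_flags = estimate_burst_size(assay)
    if_calc, _ = inducible_fraction_calculated(assay)
    if_assumed, if_flags = inducible_fraction_assumed(assay, assumed_bz)
    if assay.vc > 0:
        pct, pct_flags = percent_induction_increase(assay)
    else:
        pct, pct_flags = None, frozenset()
    return InductionResult(
        delta_v=assay.vm - assay.vc,
        bz_calc=bz,
        if_calc=if_calc,
        if_assumed=if_assumed,
        pct_increase=pct,
        flags=bz_flags | if_flags | pct_flags,
    )


_ASSAY_COLUMNS = ("v_control", "v_mitc", "b_control", "b_mitc")


def analyze_assay_table(
    table: pd.DataFrame, assumed_bz: float = DEFAULT_ASSUMED_BURST_SIZE
) -> pd.DataFrame:
    """Per-sample induction statistics for an assay table.

    `table` needs columns ``v_control, v_mitc, b_control, b_mitc`` plus any
    identifier columns (``sample_id, treatment, month, plot``), which are
    carried through.  Undefined statistics become NaN; flags are joined with
    ``;`` in a ``flags`` column.
    """
    missing = [c for c in _ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"assay table lacks columns: {missing}")
    records = []
    for _, row in table.iterrows():
        assay = InductionAssay(
            vc=row["v_control"], vm=row["v_mitc"], bc=row["b_control"], bm=row["b_mitc"]
        )
        res = analyze_assay(assay, assumed_bz)
        records.append(
            {
                "delta_v": res.delta_v,
                "bz_calc": np.nan if res.bz_calc is None else res.bz_calc,
                "if_calc": np.nan if res.if_calc is None else res.if_calc,
                "if_assumed": res.if_assumed,
                "pct_increase": np.nan if res.pct_increase is None else res.pct_increase,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    id_cols = [c for c in table.columns if c not in _ASSAY_COLUMNS]
    out = pd.concat(
        [table[id_cols].reset_index(drop=True), pd.DataFrame.from_records(records)], axis=1
    )
    return out


def summarize_induction(
    results: pd.DataFrame,
    group_cols: tuple[str, str] = ("treatment", "month"),
    value_cols: tuple[str, ...] = ("bz_calc", "if_calc", "if_assumed", "pct_increase"),
) -> pd.DataFrame:
    """Mean and sample SD of induction statistics across plot replicates.

    Groups with a single plot report SD as missing (the unreplicated-forest
    convention); empty groups are skipped with a logged warning.  NaN
    statistics (undefined burst sizes) are excluded pairwise from each mean.
    """
    rows = []
    for keys, group in results.groupby(list(group_cols), sort=False, observed=True):
        if group.empty:  # pragma: no cover - groupby does not emit empty groups
            logger.warning("empty induction group %s skipped", keys)
            continue
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row["n_plots"] = len(group)
        for col in value_cols:
            values = group[col].dropna().to_numpy(dtype=float)
            if values.size == 0:
                row[f"{col}_mean"], row[f"{col}_sd"] = np.nan, np.nan
            else:
                row[f"{col}_mean"] = float(np.mean(values))
                row[f"{col}_sd"] = float(np.std(values, ddof=1)) if values.size > 1 else np.nan
        rows.append(row)
    if not rows:
        logger.warning("summarize_induction: no non-empty groups")
        return pd.DataFrame(columns=list(group_cols))
    return pd.DataFrame(rows)
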