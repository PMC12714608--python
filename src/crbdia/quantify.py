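"""Single-point standard-addition quantification and formula composition.

The native concentration follows from the area increment after spiking a
known amount of the analyte standard into the same matrix:

    C_s = C_std * A_sample / (A_spiked - A_sample)

Because sample and spiked aliquots share the matrix, any multiplicative
matrix effect on the response cancels: the estimate is invariant to a uniform
rescaling of both areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StandardAdditionInput:
    c_std: float          # spiked standard concentration, ppm
    area_sample: float    # unspiked peak area
    area_spiked: float    # spiked peak area

    def __post_init__(self) -> None:
        if self.c_std <= 0:
            raise ValueError("c_std must be positive")
        if self.area_sample < 0 or self.area_spiked < 0:
            raise ValueError("areas must be non-negative")


def standard_addition_concentration(inp: StandardAdditionInput) -> float:
    """Native analyte concentration (ppm) by single-point standard addition.

    Exact under a linear response. An unspiked area of zero means the analyte
    is absent (returns 0). A spiked area not exceeding the unspiked one makes
    the determination invalid and raises.
    """
    if inp.area_sample == 0:
        return 0.0
    if inp.area_spiked <= inp.area_sample:
        raise ValueError("invalid spike: spiked area must exceed the unspiked area")
    return inp.c_std * inp.area_sample / (inp.area_spiked - inp.area_sample)


def quantify_table(
    unspiked: pd.DataFrame,
    spiked: pd.DataFrame,
    c_std: pd.Series,
) -> pd.DataFrame:
    """Per-(compound, sample) standard-addition concentrations.

    ``unspiked``/``spiked`` are compound x sample area tables; ``c_std`` maps
    compound -> spike concentration (ppm). Cells with an invalid spike
    (increment <= 0 despite a detected analyte) come out NaN.
    """
    out = pd.DataFrame(np.nan, index=unspiked.index, columns=unspiked.columns)
    for name in unspiked.index:
        for sid in unspiked.columns:
            a, b = unspiked.loc[name, sid], spiked.loc[name, sid]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            try:
                out.loc[name, sid] = standard_addition_concentration(
                    StandardAdditionInput(float(c_std[name]), float(a), float(b))
                )
            except ValueError:
                pass
    return out


def group_mean_concentrations(
    concentrations: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Arithmetic per-group means (compound x group), zeros included.

    Non-detects enter as zeros; only NaN cells (missing runs / invalid
    spikes) are excluded from the mean.
    """
    cols = {}
    for grp in sorted(groups.unique()):
        members = groups.index[groups == grp]
        cols[grp] = concentrations[members].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class FormulaRecipe:
    """A validation formula: named mixture of confirmed compounds."""

    name: str
    components: tuple[tuple[str, float], ...]   # (compound, concentration ppm)
    subset_rule: str                            # all_validated | majors | minors

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("formula needs at least one component")
        if any(c <= 0 for _n, c in self.components):
            raise ValueError("component concentrations must be positive")


def compose_formula(
    validated: list[tuple[str, int, float]],
    rule: str,
    majors_list: list[str] | None = None,
    name: str | None = None,
) -> FormulaRecipe:
    """Build a formula from level-1-validated compounds.

    ``validated`` holds (compound, annotation level, concentration ppm);
    only level-1 entries are eligible. ``all_validated`` takes every entry,
    ``majors`` exactly the ``majors_list`` members, ``minors`` the complement
    — so majors and minors partition the validated set.
    """
    if rule not in ("all_validated", "majors", "minors"):
        raise ValueError(f"unknown subset rule {rule!r}")
    if any(level != 1 for _n, level, _c in validated):
        raise ValueError("formula composition requires level-1 entries only")
    names = [n for n, _l, _c in validated]
    conc = {n: c for n, _l, c in validated}
    if rule in ("majors", "minors"):
        majors = list(majors_list or [])
        missing = [m for m in majors if m not in conc]
        if missing:
            raise ValueError(f"majors not among validated compounds: {missing}")
        chosen = majors if rule == "majors" else [n for n in names if n not in set(majors)]
    else:
        chosen = names
    return FormulaRecipe(
        name=name or rule,
        components=tuple((n, conc[n]) for n in chosen),
        subset_rule=rule,
    )
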