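"""Treatment-versus-control statistics for the temperature-stress design.

Each strain's treatments (e.g. high and low temperature) are compared
against the same strain's control condition, parameter by parameter:
means +- sample SD (n - 1 denominator), signed percent change, fold
change, and a two-sided Welch unequal-variance t-test.  Welch's test is
used because replicate groups are tiny (n = 3) and equal variances cannot
be assumed; no multiple-testing correction is applied, mirroring the
per-comparison starring convention of stress-physiology reports (a
documented limitation).  Significance stars follow the usual thresholds:
``**`` for p < 0.01, ``*`` for 0.01 <= p < 0.05, ``ns`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assays import ANALYTES, percent_change
from .errors import ConfigurationError, EmptyInputError, InsufficientReplicatesError
from .jip_test import PARAMETER_ORDER
from .quenching import fold_change

__all__ = [
    "ConditionComparison",
    "summarize",
    "welch_test",
    "significance_label",
    "compare_conditions",
    "melt_parameters",
]

#: Default report order: JIP parameters, then NPQ, then the assay analytes.
DEFAULT_PARAMETER_ORDER = [*PARAMETER_ORDER, "NPQ", *ANALYTES]

COMPARISON_COLUMNS = [
    "parameter",
    "strain",
    "control_label",
    "treatment_label",
    "control_mean",
    "control_sd",
    "treatment_mean",
    "treatment_sd",
    "n_control",
    "n_treatment",
    "percent_change",
    "fold_change",
    "p_value",
    "significance",
]


@dataclass(frozen=True)
class ConditionComparison:
    """Summary of one parameter, one strain, treatment vs control."""

    parameter: str
    strain: str
    control_label: str
    treatment_label: str
    control_mean: float
    control_sd: float
    treatment_mean: float
    treatment_sd: float
    n_control: int
    n_treatment: int
    percent_change: float
    fold_change: float
    p_value: float
    significance: str


def summarize(values) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD (ddof = 1; zero when n = 1) and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot summarize an empty collection")
    mean = float(arr.mean())
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return mean, sd, int(arr.size)


def welch_test(control, treatment) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Degrees of freedom follow Welch-Satterthwaite.  When both groups have
    zero variance the test statistic is undefined; the limit is reported
    instead: p = 1 for equal means, p = 0 for different means.
    """
    a = np.asarray(list(control), dtype=float)
    b = np.asarray(list(treatment), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"Welch's test needs n >= 2 per group (got {a.size} and {b.size})"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def significance_label(p: float, p_star: float = 0.05, p_double: float = 0.01) -> str:
    """Star annotation: '**' if p < p_double, '*' if p < p_star, else 'ns'."""
    if not 0 < p_double < p_star < 1:
        raise ConfigurationError(f"thresholds must satisfy 0 < {p_double} < {p_star} < 1")
    if p < p_double:
        return "**"
    if p < p_star:
        return "*"
    return "ns"


def melt_parameters(
    jip_table: pd.DataFrame | None = None,
    npq_table: pd.DataFrame | None = None,
    assay_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-sample tables into one long (strain, treatment, replicate,
    parameter, value) table ready for :func:`compare_conditions`.

    ``jip_table`` is the wide per-sample output of ``batch_jip``;
    ``npq_table`` needs an ``npq`` column; ``assay_table`` is the tidy
    analyte/value layout.
    """
    pieces = []
    if jip_table is not None and len(jip_table):
        params = [p for p in PARAMETER_ORDER if p in jip_table.columns]
        pieces.append(
            jip_table.melt(
                id_vars=["strain", "treatment", "replicate"],
                value_vars=params,
                var_name="parameter",
                value_name="value",
            )
        )
    if npq_table is not None and len(npq_table):
        pieces.append(
            npq_table.assign(parameter="NPQ", value=npq_table["npq"])[
                ["strain", "treatment", "replicate", "parameter", "value"]
            ]
        )
    if assay_table is not None and len(assay_table):
        pieces.append(
            assay_table.rename(columns={"analyte": "parameter"})[
                ["strain", "treatment", "replicate", "parameter", "value"]
            ]
        )
    if not pieces:
        raise EmptyInputError("no input tables to compare")
    return pd.concat(pieces, ignore_index=True)


def compare_conditions(
    samples: pd.DataFrame,
    control_label: str = "MT",
    parameter_order: list[str] | None = None,
    p_star: float = 0.05,
    p_double: float = 0.01,
) -> pd.DataFrame:
    """Compare every strain x treatment x parameter against the control.

    ``samples`` is a long table with columns ``strain, treatment,
    replicate, parameter, value``.  For each strain, every non-control
    treatment is compared against that strain's control condition.  Row
    order is deterministic: strain, then treatment (alphabetical), then
    parameters in report order (JIP parameters, NPQ, assay analytes;
    unknown parameters follow alphabetically).

    Raises :class:`ConfigurationError` when a strain lacks control rows.
    """
    if parameter_order is None:
        parameter_order = DEFAULT_PARAMETER_ORDER
    required = {"strain", "treatment", "replicate", "parameter", "value"}
    missing = required - set(samples.columns)
    if missing:
        raise ConfigurationError(f"comparison input missing column(s) {sorted(missing)}")

    known = {p: i for i, p in enumerate(parameter_order)}

    def param_key(p: str):
        return (known.get(p, len(known)), p)

    rows = []
    for strain in sorted(samples["strain"].unique()):
        sub = samples[samples["strain"] == strain]
        control = sub[sub["treatment"] == control_label]
        if control.empty:
            raise ConfigurationError(
                f"strain {strain!r} has no rows for control condition {control_label!r}"
            )
        treatments = sorted(t for t in sub["treatment"].unique() if t != control_label)
        for treatment in treatments:
            treated = sub[sub["treatment"] == treatment]
            params = sorted(
                set(control["parameter"]) & set(treated["parameter"]), key=param_key
            )
            for parameter in params:
                c_vals = control.loc[control["parameter"] == parameter, "value"].to_numpy(float)
                t_vals = treated.loc[treated["parameter"] == parameter, "value"].to_numpy(float)
                c_mean, c_sd, n_c = summarize(c_vals)
                t_mean, t_sd, n_t = summarize(t_vals)
                p = welch_test(c_vals, t_vals)
                rows.append(
                    ConditionComparison(
                        parameter=parameter,
                        strain=strain,
                        control_label=control_label,
                        treatment_label=treatment,
                        control_mean=c_mean,
                        control_sd=c_sd,
                        treatment_mean=t_mean,
                        treatment_sd=t_sd,
                        n_control=n_c,
                        n_treatment=n_t,
                        percent_change=percent_change(c_mean, t_mean),
                        fold_change=fold_change(c_mean, t_mean),
                        p_value=p,
                        significance=significance_label(p, p_star, p_double),
                    ).__dict__
                )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
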