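"""Interaction-energy benchmark protocol.

Per-structure interaction energies from different methods (model potentials
evaluated here, or electronic-structure values ingested from files — never
computed) are compared against one designated reference method:

* percentage deviations ``delta = 100 * (E_method - E_ref) / |E_ref|`` at
  equilibrium structures, summarized per halide ion as max/mean |delta|;
* mean absolute errors along ion-displacement scans (non-equilibrium
  configurations);
* normalized average-error bars (max over methods = 1 per panel) and
  correlation summaries (slope, intercept, RMSD) for model-vs-reference
  scatter plots.

All numbers land in TSV files first; plotting is a thin optional layer on
top of the tables, so nothing downstream ever parses an image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import HALIDES
from .errors import DataError, FormatError
from .geometry import ClusterConfiguration
from .parameters import IonWaterParameters
from .potential import interaction_energy

__all__ = [
    "MethodEnergyTable",
    "ComparisonReport",
    "read_method_energies",
    "write_method_energies",
    "percent_delta",
    "scan_error_summary",
    "comparison_report",
    "model_energy_table",
]


@dataclass
class MethodEnergyTable:
    """Per-structure interaction energies for one named method, kcal/mol."""

    method_name: str
    entries: dict = field(default_factory=dict)  # structure_id -> energy
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, e in self.entries.items():
            if not np.isfinite(e):
                raise DataError(f"{self.method_name}: non-finite energy for {sid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def series(self) -> pd.Series:
        return pd.Series(self.entries, name=self.method_name, dtype=float)


def read_method_energies(path, method_name: str | None = None) -> MethodEnergyTable:
    """Read a TSV with columns structure_id, energy_kcal_mol (+ metadata).

    Duplicate structure ids and non-numeric energies are format errors. The
    method name defaults to the file stem.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    required = {"structure_id", "energy_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dup = df["structure_id"][df["structure_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate structure_id {dup.iloc[0]!r}")
    energies = pd.to_numeric(df["energy_kcal_mol"], errors="coerce")
    bad = df.index[energies.isna()]
    if len(bad):
        raise FormatError(f"{path}: non-numeric energy in row {bad[0] + 2}")
    meta_cols = [c for c in df.columns if c not in required]
    metadata = {c: df[c].tolist() for c in meta_cols}
    return MethodEnergyTable(
        method_name=method_name or Path(path).stem,
        entries=dict(zip(df["structure_id"].astype(str), energies.astype(float))),
        metadata=metadata,
    )


def write_method_energies(table: MethodEnergyTable, path) -> None:
    df = pd.DataFrame(
        {
            "structure_id": list(table.entries.keys()),
            "energy_kcal_mol": list(table.entries.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Elementary comparisons


def percent_delta(model: MethodEnergyTable, reference: MethodEnergyTable) -> pd.Series:
    """delta = 100 * (E_model - E_ref) / |E_ref| on shared structures, %.

    Structures with a zero reference energy are skipped with a warning
    (division undefined); disjoint tables give an empty result + warning.
    """
    shared = sorted(set(model.entries) & set(reference.entries))
    if not shared:
        warnings.warn(
            f"no shared structures between {model.method_name!r} and "
            f"{reference.method_name!r}",
            stacklevel=2,
        )
        return pd.Series(dtype=float, name=model.method_name)
    out = {}
    for sid in shared:
        e_ref = reference.entries[sid]
        if e_ref == 0.0:
            warnings.warn(
                f"reference energy is zero for structure {sid!r}; delta undefined",
                stacklevel=2,
            )
            continue
        out[sid] = 100.0 * (model.entries[sid] - e_ref) / abs(e_ref)
    return pd.Series(out, name=model.method_name, dtype=float)


def scan_error_summary(model_energies, reference_energies) -> float:
    """Mean absolute deviation over identical scan points, kcal/mol."""
    m = pd.Series(model_energies, dtype=float)
    r = pd.Series(reference_energies, dtype=float)
    if len(m) == 0:
        raise DataError("empty scan series")
    if len(m) != len(r) or (
        hasattr(m.index, "equals") and not m.index.equals(r.index)
    ):
        raise DataError("scan point sets differ between model and reference")
    return float(np.mean(np.abs(m.values - r.values)))


def _ion_of(structure_id: str) -> str:
    """Ion tag from a structure id of the form '<ion>_...' (else 'all')."""
    head = structure_id.split("_", 1)[0].split("-", 1)[0]
    return head if head in HALIDES else "all"


# ---------------------------------------------------------------------------
# Full report


@dataclass
class ComparisonReport:
    """All benchmark tables for a set of methods against one reference."""

    reference_method: str
    per_structure_delta: pd.DataFrame  # rows: structure_id; cols: method
    per_ion_summary: pd.DataFrame  # rows: (ion, method); max/mean |delta|
    scan_summaries: pd.DataFrame  # rows: (scan, method); MAE kcal/mol
    normalized_errors: pd.DataFrame  # per panel (ion or scan), in [0, 1]
    correlations: pd.DataFrame  # slope/intercept/rmsd per method

    def write(self, out_dir) -> list[Path]:
        """Write every table as TSV; byte-identical for identical inputs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("per_structure_delta", self.per_structure_delta),
            ("per_ion_summary", self.per_ion_summary),
            ("scan_summaries", self.scan_summaries),
            ("normalized_errors", self.normalized_errors),
            ("correlations", self.correlations),
        ]:
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", float_format="%.10g")
            written.append(path)
        return written


def _normalize(values: pd.Series) -> pd.Series:
    mx = values.max()
    return values / mx if mx > 0 else values * 0.0


def comparison_report(
    tables: list[MethodEnergyTable],
    reference: str,
    scans: dict | None = None,
) -> ComparisonReport:
    """Assemble the full benchmark report.

    ``tables`` must include the reference method by name. ``scans``
    optionally maps scan labels to {method_name: series-of-energies over
    identical scan points} for the non-equilibrium error summaries.
    """
    by_name = {t.method_name: t for t in tables}
    if reference not in by_name:
        raise DataError(f"reference method {reference!r} not among the tables")
    ref = by_name[reference]
    models = [t for t in tables if t.method_name != reference]

    deltas = {}
    for t in models:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            deltas[t.method_name] = percent_delta(t, ref)
    per_structure = pd.DataFrame(deltas).sort_index()

    rows = []
    for method, series in per_structure.items():
        clean = series.dropna()
        ions = clean.index.map(_ion_of)
        for ion in sorted(set(ions)):
            sel = clean[ions == ion]
            rows.append(
                {
                    "ion": ion,
                    "method": method,
                    "max_abs_delta_pct": float(sel.abs().max()) if len(sel) else np.nan,
                    "mean_abs_delta_pct": float(sel.abs().mean()) if len(sel) else np.nan,
                    "n_structures": int(len(sel)),
                }
            )
    per_ion = pd.DataFrame(rows, columns=["ion", "method", "max_abs_delta_pct",
                                          "mean_abs_delta_pct", "n_structures"])
    if len(per_ion):
        per_ion = per_ion.sort_values(["ion", "method"]).set_index(["ion", "method"])

    scan_rows = []
    if scans:
        for scan_label in sorted(scans):
            methods = scans[scan_label]
            if reference not in methods:
                raise DataError(f"scan {scan_label!r} lacks the reference series")
            for method in sorted(methods):
                if method == reference:
                    continue
                scan_rows.append(
                    {
                        "scan": scan_label,
                        "method": method,
                        "mae_kcal_mol": scan_error_summary(methods[method], methods[reference]),
                    }
                )
    scan_summaries = pd.DataFrame(scan_rows, columns=["scan", "method", "mae_kcal_mol"])
    if len(scan_summaries):
        scan_summaries = scan_summaries.set_index(["scan", "method"])

    # normalized average errors: one panel per ion (equilibrium deltas) and,
    # when scans are given, one panel per scan (MAE); max over methods = 1
    norm_rows = []
    if len(per_ion):
        for ion in per_ion.index.get_level_values("ion").unique():
            sub = per_ion.loc[ion]["mean_abs_delta_pct"]
            normed = _normalize(sub)
            for method, v in normed.items():
                norm_rows.append({"panel": f"ion:{ion}", "method": method, "normalized_error": float(v)})
    if len(scan_summaries):
        for scan_label in scan_summaries.index.get_level_values("scan").unique():
            sub = scan_summaries.loc[scan_label]["mae_kcal_mol"]
            normed = _normalize(sub)
            for method, v in normed.items():
                norm_rows.append({"panel": f"scan:{scan_label}", "method": method,
                                  "normalized_error": float(v)})
    normalized = pd.DataFrame(norm_rows, columns=["panel", "method", "normalized_error"])
    if len(normalized):
        normalized = normalized.set_index(["panel", "method"])

    corr_rows = []
    ref_series = ref.series()
    for t in models:
        s = t.series()
        shared = sorted(set(s.index) & set(ref_series.index))
        if len(shared) >= 2:
            x = ref_series[shared].values
            y = s[shared].values
            slope, intercept = np.polyfit(x, y, 1)
            rmsd = float(np.sqrt(np.mean((y - x) ** 2)))
            corr_rows.append(
                {"method": t.method_name, "slope": float(slope),
                 "intercept": float(intercept), "rmsd_kcal_mol": rmsd,
                 "n_structures": len(shared)}
            )
    correlations = pd.DataFrame(
        corr_rows, columns=["method", "slope", "intercept", "rmsd_kcal_mol", "n_structures"]
    )
    if len(correlations):
        correlations = correlations.set_index("method")

    return ComparisonReport(
        reference_method=reference,
        per_structure_delta=per_structure,
        per_ion_summary=per_ion,
        scan_summaries=scan_summaries,
        normalized_errors=normalized,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------
# Model evaluation


def model_energy_table(
    params: IonWaterParameters,
    water_model,
    structures: list[ClusterConfiguration],
    method_name: str | None = None,
) -> MethodEnergyTable:
    """Interaction energies of the model potential over the structures.

    Structure ids are taken from the configuration labels (falling back to
    the list position when a label is empty).
    """
    entries = {}
    for i, config in enumerate(structures):
        sid = config.label or f"structure_{i}"
        if sid in entries:
            raise DataError(f"duplicate structure label {sid!r}")
        entries[sid] = interaction_energy(params, water_model, config)
    return MethodEnergyTable(
        method_name=method_name or f"i-ttm[{params.ion}]",
        entries=entries,
        metadata={"model": params.model, "ion": params.ion},
    )


# ---------------------------------------------------------------------------
# Optional plots (thin layer; numbers always come from the tables above)


def plot_correlation(report: ComparisonReport, tables, path) -> None:
    """Model-vs-reference scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_name = {t.method_name: t for t in tables}
    ref = by_name[report.reference_method].series()
    fig, ax = plt.subplots(figsize=(5, 5))
    lo, hi = ref.min(), ref.max()
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8, label="reference")
    for name, t in by_name.items():
        if name == report.reference_method:
            continue
        s = t.series()
        shared = sorted(set(s.index) & set(ref.index))
        ax.plot(ref[shared], s[shared], "o", ms=4, label=name)
    ax.set_xlabel("reference interaction energy (kcal/mol)")
    ax.set_ylabel("method interaction energy (kcal/mol)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_normalized_errors(report: ComparisonReport, path) -> None:
    """Bar chart of the normalized average errors per panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.normalized_errors.reset_index()
    if not len(df):
        raise DataError("report has no normalized errors to plot")
    panels = df["panel"].unique()
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3), squeeze=False)
    for ax, panel in zip(axes[0], panels):
        sub = df[df["panel"] == panel]
        ax.bar(sub["method"], sub["normalized_error"])
        ax.set_title(panel, fontsize=8)
        ax.set_ylim(0, 1.05)
        ax.tick_params(axis="x", rotation=60, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
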