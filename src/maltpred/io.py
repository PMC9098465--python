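"""Readers and writers for the package's tab-delimited table formats.

All tables are UTF-8, tab-delimited, '.' decimal, with a header row, and
round-trip exactly through these functions. The spectra format is: first
column ``plot_id``, remaining column headers the ppm values (ascending,
serialized with 4 decimals — lossless for the synthetic axes generated
here); intensities are serialized at full double precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kernel import KernelMatrix
from .preprocess import SpectraMatrix, StandardizedMatrix

__all__ = [
    "write_spectra_table",
    "read_spectra_table",
    "write_phenotype_table",
    "read_phenotype_table",
    "write_standardized_table",
    "read_standardized_table",
    "write_kernel_table",
    "read_kernel_table",
    "write_truth_tables",
    "write_dataset",
    "write_manifest",
]

META_COLUMNS = ["plot_id", "line_id", "location", "year", "trial"]


def _format_matrix_rows(ids, X) -> list[str]:
    return [
        "\t".join([str(pid)] + [np.format_float_scientific(v, trim="-") for v in row])
        for pid, row in zip(ids, X)
    ]


def write_spectra_table(spectra: SpectraMatrix, path) -> None:
    path = Path(path)
    header = "plot_id\t" + "\t".join(f"{p:.4f}" for p in spectra.ppm)
    lines = [header] + _format_matrix_rows(spectra.plot_ids, spectra.intensities)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectra_table(path) -> SpectraMatrix:
    """Read a spectra table; ppm columns are re-sorted ascending (with a
    warning) if needed; duplicate plot ids and non-numeric cells raise."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "plot_id":
        raise ValueError(f"{path}: first column must be 'plot_id', got {df.columns[0]!r}")
    plot_ids = df["plot_id"].astype(str).tolist()
    dupes = df["plot_id"][df["plot_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate plot_id(s): {dupes}")
    try:
        ppm = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric ppm column header: {exc}") from exc
    X = np.empty((len(df), ppm.size))
    for j, col in enumerate(df.columns[1:]):
        try:
            # numpy's parser round-trips the serialized doubles exactly
            X[:, j] = df[col].to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna()].index[0])
            raise ValueError(
                f"{path}: non-numeric intensity at row {row + 2} (plot "
                f"{plot_ids[row]!r}), column {col!r}"
            ) from None
    order = np.argsort(ppm, kind="stable")
    if not np.array_equal(order, np.arange(ppm.size)):
        warnings.warn(f"{path}: ppm columns not ascending; re-sorting", stacklevel=2)
        ppm, X = ppm[order], X[:, order]
    return SpectraMatrix(plot_ids, ppm, X)


def write_phenotype_table(meta: pd.DataFrame, phenotypes: pd.DataFrame, path) -> None:
    """Write plot metadata joined with trait values, one row per plot."""
    merged = meta.merge(phenotypes, on="plot_id", validate="one_to_one")
    merged.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotype_table(path, spectra_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the meta + phenotype table -> (meta, phenotypes).

    Trait columns are everything beyond the metadata columns; plots with a
    missing trait value are retained (downstream analyses drop them
    per-trait). If ``spectra_ids`` is given, plot ids must match it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["plot_id"] = df["plot_id"].astype(str)
    required = ["plot_id", "line_id", "location", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "trial" not in df.columns:
        df["trial"] = "T01"
    traits = [c for c in df.columns if c not in META_COLUMNS]
    if not traits:
        raise ValueError(f"{path}: no trait columns found")
    if spectra_ids is not None:
        offenders = sorted(set(df["plot_id"]) ^ set(str(s) for s in spectra_ids))
        if offenders:
            raise ValueError(
                f"{path}: plot_ids do not match the spectra table; offenders: "
                f"{offenders[:20]}{'...' if len(offenders) > 20 else ''}"
            )
    meta = df[META_COLUMNS].copy()
    phenotypes = df[["plot_id"] + traits].copy()
    return meta, phenotypes


def write_standardized_table(Q: StandardizedMatrix, path) -> None:
    """Serialize a standardized feature matrix in the spectra-table layout
    (statistics are not stored; the matrix itself is already centered and
    scaled)."""
    path = Path(path)
    header = "plot_id\t" + "\t".join(f"{p:.4f}" for p in Q.ppm)
    lines = [header] + _format_matrix_rows(Q.plot_ids, Q.Q)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_standardized_table(path) -> StandardizedMatrix:
    s = read_spectra_table(path)
    X = s.intensities
    return StandardizedMatrix(
        plot_ids=s.plot_ids,
        ppm=s.ppm,
        Q=X,
        feature_means=X.mean(axis=0),
        feature_sds=X.std(axis=0, ddof=0),
    )


def write_kernel_table(kernel: KernelMatrix, path) -> None:
    path = Path(path)
    header = "sample_id\t" + "\t".join(kernel.sample_ids)
    lines = [header] + _format_matrix_rows(kernel.sample_ids, kernel.M)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_kernel_table(path, m_features: int = 0) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return KernelMatrix(
        sample_ids=[str(c) for c in df.columns],
        M=df.to_numpy(dtype=float),
        m_features=m_features,
    )


def write_truth_tables(dataset, out_dir) -> None:
    """Write the generator's truth (per-plot latent values and per-trait
    effect vectors) as delimited tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = dataset.truth
    if t is None:
        raise ValueError("dataset has no stored truth")
    per_plot = pd.DataFrame({"plot_id": dataset.spectra.plot_ids})
    per_plot["dilution"] = t.dilutions.to_numpy()
    per_plot["shift_bins"] = t.shifts.to_numpy()
    for trait in t.m.columns:
        per_plot[f"m_{trait}"] = t.m[trait].to_numpy()
        per_plot[f"e_{trait}"] = t.e[trait].to_numpy()
    per_plot.to_csv(out / "truth_plots.tsv", sep="\t", index=False, float_format="%.17g")
    t.betas.rename_axis("metabolite").to_csv(
        out / "truth_effects.tsv", sep="\t", float_format="%.17g"
    )
    t.concentrations.rename_axis("plot_id").to_csv(
        out / "truth_concentrations.tsv", sep="\t", float_format="%.17g"
    )


def write_dataset(dataset, out_dir) -> dict[str, Path]:
    """Write spectra, meta+phenotypes, and truth tables to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out / "spectra.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_spectra_table(dataset.spectra, paths["spectra"])
    write_phenotype_table(dataset.meta, dataset.phenotypes, paths["phenotypes"])
    if dataset.truth is not None:
        write_truth_tables(dataset, out)
        paths["truth"] = out / "truth_plots.tsv"
    return paths


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: dict[str, str | Path]) -> Path:
    """Machine-readable run manifest: resolved configuration plus input
    checksums, written next to the outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _checksum(Path(p))}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return path
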