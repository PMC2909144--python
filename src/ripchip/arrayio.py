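"""Readers and writers for the file formats the pipeline touches.

Two-color scan tables are handled in a GenePix-results (GPR) dialect: a
tab-delimited file whose header names the per-spot intensity columns. Only
five columns are required (``ID`` plus the four median foreground/background
intensities); anything else is carried along and ignored. Gene sets use the
GMT format, expression matrices are plain TSV with the probe id in the first
column, and clustered matrices can be exported as CDT/GTR/ATR files for
Java TreeView.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("IP", "mock", "total")

#: column names of the GPR dialect written by the simulator, mapped to the
#: ArrayScan fields they populate.  Cy3 (532 nm) is the experimental sample,
#: Cy5 (635 nm) the common reference RNA.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "sample_fg": "F532 Median",
    "sample_bg": "B532 Median",
    "ref_fg": "F635 Median",
    "ref_bg": "B635 Median",
}

GPR_COLUMNS = ["Block", "Row", "Column", "ID", "Name",
               "F532 Median", "B532 Median", "F635 Median", "B635 Median"]


@dataclass
class ArrayScan:
    """One hybridized array: per-probe two-channel intensities plus metadata.

    Intensities are raw fluorescence units; ``sample_*`` is the Cy3
    experimental channel, ``ref_*`` the Cy5 universal-reference channel.
    """

    probe_ids: np.ndarray
    sample_fg: np.ndarray
    sample_bg: np.ndarray
    ref_fg: np.ndarray
    ref_bg: np.ndarray
    role: str
    replicate: int

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        n = len(self.probe_ids)
        for name in ("sample_fg", "sample_bg", "ref_fg", "ref_bg"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {v.shape}")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, v)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered unique member ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def write_scan(scan: ArrayScan, path: str | Path) -> None:
    """Write a scan as a GPR-style tab-delimited table (single print block)."""
    n = len(scan)
    df = pd.DataFrame({
        "Block": np.ones(n, dtype=int),
        "Row": np.arange(n) // 100 + 1,
        "Column": np.arange(n) % 100 + 1,
        "ID": scan.probe_ids,
        "Name": scan.probe_ids,
        "F532 Median": scan.sample_fg,
        "B532 Median": scan.sample_bg,
        "F635 Median": scan.ref_fg,
        "B635 Median": scan.ref_bg,
    })
    df.to_csv(path, sep="\t", index=False)


def read_scan(path: str | Path, channel_map: Mapping[str, str] | None = None,
              role: str = "IP", replicate: int = 1) -> ArrayScan:
    """Read a GPR-style tab-delimited scan file.

    ``channel_map`` assigns which header columns hold the sample/reference
    foreground and background intensities; defaults to the dialect written by
    :func:`write_scan`. Parsing is strict: a missing mapped column, duplicate
    header, or non-numeric intensity raises ``ValueError``.
    """
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate header column(s): {dups}")
    if "ID" not in df.columns:
        raise ValueError("missing required column 'ID'")
    intens = {}
    for fld, col in cmap.items():
        if col not in df.columns:
            raise ValueError(f"missing mapped column {col!r} (for {fld})")
        try:
            intens[fld] = df[col].astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"non-numeric intensity in column {col!r}: {exc}") from None
    return ArrayScan(probe_ids=df["ID"].to_numpy(dtype=object),
                     role=role, replicate=replicate, **intens)


def write_manifest(entries: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    """Write a samples manifest: one row per array file (file, role, replicate)."""
    with open(path, "w") as fh:
        fh.write("file\trole\treplicate\n")
        for fname, role, rep in entries:
            fh.write(f"{fname}\t{role}\t{rep}\n")


def read_manifest(path: str | Path) -> list[tuple[str, str, int]]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["file", "role", "replicate"]:
            raise ValueError(f"unexpected manifest header: {header}")
        for line in fh:
            if not line.strip():
                continue
            fname, role, rep = line.rstrip("\n").split("\t")[:3]
            out.append((fname, role, int(rep)))
    return out


def read_scans(manifest_path: str | Path,
               channel_map: Mapping[str, str] | None = None) -> list[ArrayScan]:
    """Read every scan listed in a manifest (paths relative to the manifest)."""
    base = Path(manifest_path).parent
    scans = []
    for fname, role, rep in read_manifest(manifest_path):
        scans.append(read_scan(base / fname, channel_map, role=role, replicate=rep))
    return scans


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, tab-separated members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT line needs name, description and >=1 member")
            name, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"line {lineno}: gene set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_matrix(probe_ids: Sequence[str], sample_names: Sequence[str],
                 values: np.ndarray, path: str | Path) -> None:
    """Write a probes x samples matrix as TSV, probe ids in the first column."""
    df = pd.DataFrame(np.asarray(values), index=list(probe_ids),
                      columns=list(sample_names))
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def _check_permutation(order: Sequence[int], n: int, what: str) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError(f"{what} is not a permutation of 0..{n - 1}")
    return order


def write_treeview(probe_ids: Sequence[str], sample_names: Sequence[str],
                   values: np.ndarray, row_order: Sequence[int],
                   col_order: Sequence[int], path_prefix: str | Path,
                   row_tree: np.ndarray | None = None,
                   col_tree: np.ndarray | None = None) -> list[Path]:
    """Export a clustered matrix in Java TreeView's CDT (+ optional GTR/ATR) format.

    ``row_tree``/``col_tree`` are scipy linkage matrices; when given, the GID /
    AID columns reference the tree node ids so TreeView can draw dendrograms.
    """
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    row_order = _check_permutation(row_order, n_rows, "row_order")
    col_order = _check_permutation(col_order, n_cols, "col_order")
    prefix = Path(path_prefix)
    written = []

    cdt_path = prefix.with_suffix(".cdt")
    with open(cdt_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"]
        header += [str(sample_names[j]) for j in col_order]
        w.writerow(header)
        if col_tree is not None:
            w.writerow(["AID", "", "", ""] +
                       [f"ARRY{j}X" for j in col_order])
        w.writerow(["EWEIGHT", "", "", ""] + ["1"] * n_cols)
        for i in row_order:
            row = [f"GENE{i}X", str(probe_ids[i]), str(probe_ids[i]), "1"]
            row += [f"{values[i, j]:.6g}" for j in col_order]
            w.writerow(row)
    written.append(cdt_path)

    def _write_tree(tree: np.ndarray, leaf_prefix: str, suffix: str) -> Path:
        path = prefix.with_suffix(suffix)
        n_leaves = tree.shape[0] + 1
        with open(path, "w") as fh:
            for k, (a, b, dist, _) in enumerate(tree):
                def node(idx: float) -> str:
                    idx = int(idx)
                    return (f"{leaf_prefix}{idx}X" if idx < n_leaves
                            else f"NODE{idx - n_leaves + 1}X")
                # TreeView expects a correlation-like score in [-1, 1]
                score = 1.0 - float(dist)
                fh.write(f"NODE{k + 1}X\t{node(a)}\t{node(b)}\t{score:.6g}\n")
        return path

    if row_tree is not None:
        written.append(_write_tree(np.asarray(row_tree), "GENE", ".gtr"))
    if col_tree is not None:
        written.append(_write_tree(np.asarray(col_tree), "ARRY", ".atr"))
    return written


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA records as {id: sequence} via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
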