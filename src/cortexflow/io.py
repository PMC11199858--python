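"""Readers and writers for link lists, adjacency matrices and metadata.

File dialects
-------------
* Link list: delimited text with columns ``source target weight
  [distance_mm]``; header optional, ``#`` comment lines ignored, delimiter
  sniffed among tab / comma / whitespace.  Labels are case-sensitive.
* Adjacency: labelled delimited matrix (CSV/TSV), row labels (sources) in the
  first column, column labels (targets) in the header.  May be rectangular,
  e.g. 116 sources x 55 measured targets.
* Node metadata: ``label region x_mm y_mm z_mm measured``.
* Injection records: ``target injection_volume LNi LNe LNtot``.
"""

from __future__ import annotations

import io as _io
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, InjectionRecord, compute_distances

__all__ = [
    "read_link_list",
    "write_link_list",
    "read_adjacency",
    "write_adjacency",
    "read_node_meta",
    "write_node_meta",
    "read_injection_records",
    "write_injection_records",
]


def _data_lines(path: str) -> list[tuple[int, str]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


def _sniff_delimiter(line: str) -> str | None:
    """Return '\\t' or ',' if present, else None (split on any whitespace)."""
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_link_list(
    path: str,
    node_meta: str | None = None,
    aggregate: str | None = None,
    weight_kind: str = "LNe",
) -> Connectome:
    """Read a directed link list into a :class:`Connectome`.

    Nodes are the union of all source and target labels (plus any labels in
    the optional ``node_meta`` file); the measured flag is set for every
    label that appears as a target.  Duplicate ``(source, target)`` rows are
    an error unless ``aggregate="sum"`` is requested.  If a fourth column is
    present it is taken as the link length in mm and mirrored into ``D``.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: no links parsed")
    delim = _sniff_delimiter(lines[0][1])

    rows: list[tuple[str, str, float, float | None]] = []
    for lineno, line in lines:
        toks = [t.strip() for t in (line.split(delim) if delim else line.split())]
        toks = [t for t in toks if t != ""]
        if len(toks) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(toks)}")
        if not _is_number(toks[2]):
            if not rows and lineno == lines[0][0]:
                continue  # header row
            raise ValueError(f"{path}:{lineno}: non-numeric weight {toks[2]!r}")
        s, t, w = toks[0], toks[1], float(toks[2])
        if w < 0:
            raise ValueError(f"{path}:{lineno}: negative weight {w}")
        if s == t:
            raise ValueError(f"{path}:{lineno}: self-link {s!r} -> {t!r}")
        d = float(toks[3]) if len(toks) >= 4 and _is_number(toks[3]) else None
        rows.append((s, t, w, d))
    if not rows:
        raise ValueError(f"{path}: no links parsed")

    labels: list[str] = []
    seen: set[str] = set()
    meta_df = None
    if node_meta is not None:
        meta_df = read_node_meta(node_meta)
        for lab in meta_df.index:
            if lab not in seen:
                labels.append(lab)
                seen.add(lab)
    for s, t, _, _ in rows:
        for lab in (s, t):
            if lab not in seen:
                labels.append(lab)
                seen.add(lab)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    W = np.zeros((n, n))
    D = np.full((n, n), np.nan)
    np.fill_diagonal(D, 0.0)
    have_dist = False
    filled = set()
    for s, t, w, d in rows:
        i, j = idx[s], idx[t]
        if (i, j) in filled:
            if aggregate == "sum":
                W[i, j] += w
                continue
            raise ValueError(
                f"{path}: duplicate link {s!r} -> {t!r}; pass aggregate='sum' to pool"
            )
        filled.add((i, j))
        W[i, j] = w
        if d is not None:
            D[i, j] = D[j, i] = d
            have_dist = True

    measured = np.zeros(n, dtype=bool)
    for _, t, _, _ in rows:
        measured[idx[t]] = True
    coords = regions = None
    if meta_df is not None:
        coords = np.full((n, 3), np.nan)
        regions = [None] * n
        for lab, row in meta_df.iterrows():
            if lab in idx:
                i = idx[lab]
                coords[i] = [row["x_mm"], row["y_mm"], row["z_mm"]]
                regions[i] = row["region"]
                measured[i] = measured[i] or bool(row["measured"])
        if np.isnan(coords).any():
            coords = None  # incomplete coordinate coverage
    c = Connectome(
        labels=labels,
        W=W,
        weight_kind=weight_kind,  # type: ignore[arg-type]
        measured=measured,
        coords=coords,
        regions=regions,
        D=D if have_dist else None,
    )
    if c.coords is not None and c.D is None:
        c = compute_distances(c)
    return c


def write_link_list(c: Connectome, path: str, delimiter: str = "\t") -> None:
    """Write non-zero links as ``source target weight [distance_mm]``."""
    with open(path, "w") as fh:
        fh.write(f"# directed link list, weight_kind={c.weight_kind}\n")
        cols = "source{0}target{0}weight".format(delimiter)
        if c.D is not None:
            cols += f"{delimiter}distance_mm"
        fh.write(cols + "\n")
        ss, tt = np.nonzero(c.W)
        for i, j in zip(ss, tt):
            row = f"{c.labels[i]}{delimiter}{c.labels[j]}{delimiter}{c.W[i, j]:.12g}"
            if c.D is not None:
                row += f"{delimiter}{c.D[i, j]:.12g}"
            fh.write(row + "\n")


def read_adjacency(path: str, weight_kind: str = "LNe") -> Connectome:
    """Read a labelled (possibly rectangular) adjacency matrix.

    Rows are sources, columns targets; labels are unioned into one node set
    and absent row/column entries are treated as zero weight.  Targets
    (column labels) are flagged measured.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        text = "".join(line for line in fh if not line.lstrip().startswith("#"))
    if not text.strip():
        raise ValueError(f"{path}: empty matrix")
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    header_labels = [t.strip() for t in header.split(sep)[1:]]
    if len(header_labels) != len(set(header_labels)):
        raise ValueError(f"{path}: duplicate row or column labels")
    df = pd.read_csv(_io.StringIO(text), sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column labels")
    try:
        vals = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric cell ({e})") from None
    if vals.isna().any().any():
        raise ValueError(f"{path}: non-numeric or missing cell")

    labels = list(df.index)
    for lab in df.columns:
        if lab not in set(labels):
            labels.append(lab)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    for lab_t in df.columns:
        j = idx[lab_t]
        for lab_s in df.index:
            W[idx[lab_s], j] = vals.at[lab_s, lab_t]
    measured = np.zeros(n, dtype=bool)
    for lab in df.columns:
        measured[idx[lab]] = True
    return Connectome(labels=labels, W=W, weight_kind=weight_kind, measured=measured)  # type: ignore[arg-type]


def write_adjacency(c: Connectome, path: str, measured_only_columns: bool = False) -> None:
    """Write the weight matrix as CSV with row (source) and column (target) labels."""
    cols = (
        [lab for lab, m in zip(c.labels, c.measured) if m]
        if measured_only_columns
        else c.labels
    )
    col_idx = [c.index(lab) for lab in cols]
    df = pd.DataFrame(c.W[:, col_idx], index=c.labels, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# adjacency: rows=source, columns=target, weight_kind={c.weight_kind}\n")
        df.to_csv(fh)


def read_node_meta(path: str) -> pd.DataFrame:
    """Read node metadata ``label region x_mm y_mm z_mm measured`` into a frame."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty metadata file")
    delim = _sniff_delimiter(lines[0][1])
    recs = []
    for lineno, line in lines:
        toks = [t.strip() for t in (line.split(delim) if delim else line.split())]
        if len(toks) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns")
        if not _is_number(toks[2]):
            continue  # header
        recs.append(
            {
                "label": toks[0],
                "region": toks[1],
                "x_mm": float(toks[2]),
                "y_mm": float(toks[3]),
                "z_mm": float(toks[4]),
                "measured": toks[5].lower() in ("1", "true", "yes"),
            }
        )
    df = pd.DataFrame(recs).set_index("label")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate labels")
    return df


def write_node_meta(c: Connectome, path: str, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["label", "region", "x_mm", "y_mm", "z_mm", "measured"]) + "\n")
        for i, lab in enumerate(c.labels):
            region = (c.regions[i] if c.regions else None) or "NA"
            xyz = c.coords[i] if c.coords is not None else (np.nan,) * 3
            fh.write(
                delimiter.join(
                    [lab, str(region)]
                    + [f"{v:.6g}" for v in xyz]
                    + ["1" if c.measured[i] else "0"]
                )
                + "\n"
            )


def read_injection_records(path: str) -> list[InjectionRecord]:
    """Read per-experiment records ``target injection_volume LNi LNe LNtot``."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty records file")
    delim = _sniff_delimiter(lines[0][1])
    out = []
    for lineno, line in lines:
        toks = [t.strip() for t in (line.split(delim) if delim else line.split())]
        if len(toks) < 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns")
        if not _is_number(toks[1]):
            continue  # header
        out.append(
            InjectionRecord(
                target=toks[0],
                injection_volume=float(toks[1]),
                LNi=float(toks[2]),
                LNe_total=float(toks[3]),
                LNtot=float(toks[4]),
            )
        )
    if not out:
        raise ValueError(f"{path}: no records parsed")
    return out


def write_injection_records(
    records: Sequence[InjectionRecord], path: str, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["target", "injection_volume", "LNi", "LNe", "LNtot"]) + "\n")
        for r in records:
            fh.write(
                delimiter.join(
                    [r.target]
                    + [f"{v:.12g}" for v in (r.injection_volume, r.LNi, r.LNe_total, r.LNtot)]
                )
                + "\n"
            )
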