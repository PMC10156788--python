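"""Subunit-occupancy sorting of symmetry-expanded cryo-EM particles.

A C4-symmetric channel particle is symmetry-expanded into four subunit
copies, each copy assigned a focused 3D class that is either ligand
"bound" or "unbound".  This module traces expanded rows back to their
original particles, canonicalizes the per-particle binding pattern
under cyclic rotation (for a tetramer: 0, 1, 2-cis, 2-trans, 3, 4 bound
copies), removes the expansion duplicates and writes one RELION-dialect
STAR file per pattern together with the pattern fractions.

Only particle metadata is handled; image-space processing (subtraction,
classification, refinement) happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ParticleTable",
    "ClassMap",
    "OccupancyPattern",
    "classify_pattern",
    "read_star",
    "write_star",
    "symmetry_expand",
    "sort_particles",
    "write_pattern_stars",
]

#: default RELION column names; override to absorb dialect drift
DEFAULT_COLUMNS = {
    "image": "rlnImageName",
    "coord_x": "rlnCoordinateX",
    "coord_y": "rlnCoordinateY",
    "micrograph": "rlnMicrographName",
    "rot": "rlnAngleRot",
    "class": "rlnClassNumber",
}


@dataclass(frozen=True)
class ClassMap:
    """Partition of focused-class ids into ligand-bound and unbound."""

    bound_classes: frozenset
    unbound_classes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound_classes", frozenset(self.bound_classes))
        object.__setattr__(self, "unbound_classes", frozenset(self.unbound_classes))
        if self.bound_classes & self.unbound_classes:
            raise ValueError("bound and unbound class sets overlap")

    def is_bound(self, class_id: int) -> bool:
        if class_id in self.bound_classes:
            return True
        if class_id in self.unbound_classes:
            return False
        raise KeyError(f"class id {class_id} not in the declared class set")


@dataclass(frozen=True)
class OccupancyPattern:
    """Canonical occupancy pattern of a cyclic ring of subunits.

    ``canonical`` is the lexicographically minimal cyclic rotation of
    the binary occupancy tuple; ``label`` is the tetramer vocabulary
    ("0", "1", "2-cis", "2-trans", "3", "4") when S = 4, otherwise
    "<count>@<canonical positions>".
    """

    label: str
    canonical: tuple

    @property
    def n_bound(self) -> int:
        return sum(self.canonical)


def _min_rotation(t: tuple) -> tuple:
    return min(tuple(t[i:] + t[:i]) for i in range(len(t)))


def classify_pattern(bound_flags, order: int = 4) -> OccupancyPattern:
    """Canonical occupancy pattern of one particle's subunit ring.

    Invariant under cyclic rotation of the flags.  For a tetramer the
    two-bound patterns split into "2-cis" (adjacent subunits) and
    "2-trans" (diagonal subunits).
    """
    flags = tuple(int(bool(f)) for f in bound_flags)
    if len(flags) != order:
        raise ValueError(f"expected {order} flags, got {len(flags)}")
    canon = _min_rotation(flags)
    k = sum(canon)
    if order == 4 and k == 2:
        label = "2-trans" if canon == (0, 1, 0, 1) else "2-cis"
    elif k in (0, 1, order - 1, order) or order != 4:
        if 1 < k < order - 1 and order != 4:
            positions = tuple(i for i, f in enumerate(canon) if f)
            label = f"{k}@{positions}"
        else:
            label = str(k)
    else:
        label = str(k)
    return OccupancyPattern(label=label, canonical=canon)


@dataclass
class ParticleTable:
    """Symmetry-expanded particle metadata with per-row subunit indices.

    ``df`` carries the raw STAR columns; ``original_particle_id`` is
    derived from the image name plus micrograph coordinates, and
    ``subunit_index`` is the rank (0..S-1) of the in-plane rotation
    angle within each particle, which orders the expanded copies
    consistently around the symmetry axis.
    """

    df: pd.DataFrame
    symmetry_order: int = 4
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        img = self.columns["image"]
        if img not in self.df.columns:
            raise ValueError(f"missing required column {img!r}")
        if "original_particle_id" not in self.df.columns:
            self.df = self.df.copy()
            self.df["original_particle_id"] = self._derive_ids()
        if "subunit_index" not in self.df.columns:
            rot = self.columns["rot"]
            if rot in self.df.columns:
                ang = self.df[rot].astype(float) % 360.0
                self.df["subunit_index"] = (
                    ang.groupby(self.df["original_particle_id"])
                    .rank(method="first").astype(int) - 1)
            else:
                self.df["subunit_index"] = (
                    self.df.groupby("original_particle_id").cumcount())

    def _derive_ids(self) -> pd.Series:
        parts = [self.df[self.columns["image"]].astype(str)]
        for key in ("micrograph", "coord_x", "coord_y"):
            col = self.columns[key]
            if col in self.df.columns:
                vals = self.df[col]
                if key.startswith("coord"):
                    vals = vals.astype(float).round(2).astype(str)
                parts.append(vals.astype(str))
        out = parts[0]
        for p in parts[1:]:
            out = out + "|" + p
        return out

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_particles(self) -> int:
        return self.df["original_particle_id"].nunique()


def read_star(path, block: str = "particles",
              columns: dict | None = None,
              symmetry_order: int = 4) -> ParticleTable:
    """Read a RELION-dialect STAR particle file.

    The ``data_particles`` block (or the sole data block of legacy
    files) is parsed; unknown columns are preserved for round-trip.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed STAR file {path}: {exc}") from exc
    blk = doc.find_block(block)
    if blk is None:
        named = [b for b in doc if b.name not in ("optics",)]
        if not named:
            raise ValueError(f"no particle data block in {path}")
        blk = named[0]
    tags = [item.loop.tags for item in blk if item.loop is not None]
    if not tags:
        raise ValueError(f"no loop in block data_{blk.name} of {path}")
    tags = tags[0]
    data = {}
    for tag in tags:
        col = blk.find_loop(tag)
        name = tag.lstrip("_")
        values = [gemmi.cif.as_string(v) for v in col]
        ser = pd.Series(values)
        try:
            ser = pd.to_numeric(ser)
        except (ValueError, TypeError):
            pass
        data[name] = ser
    df = pd.DataFrame(data)
    img = cols["image"]
    if img not in df.columns:
        raise ValueError(f"STAR file {path} lacks required column _{img}")
    return ParticleTable(df, symmetry_order=symmetry_order, columns=cols)


def write_star(df: pd.DataFrame, path, block: str = "particles") -> None:
    """Write a particle DataFrame as a RELION-dialect STAR file."""
    doc = gemmi.cif.Document()
    blk = doc.add_new_block(block)
    cols = [c for c in df.columns
            if c not in ("original_particle_id", "subunit_index", "bound")]
    loop = blk.init_loop("_", cols)
    for _, row in df[cols].iterrows():
        loop.add_row([gemmi.cif.quote(str(v)) for v in row])
    doc.write_file(str(path))


def symmetry_expand(df: pd.DataFrame, order: int = 4,
                    columns: dict | None = None) -> ParticleTable:
    """Expand one row per particle into ``order`` subunit copies.

    Copy k gets an in-plane rotation offset of k*360/order degrees,
    mirroring point-group symmetry expansion about the symmetry axis.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    rot = cols["rot"]
    out = []
    for k in range(order):
        copy = df.copy()
        base = copy[rot].astype(float) if rot in copy.columns else 0.0
        copy[rot] = (base + k * 360.0 / order) % 360.0
        out.append(copy)
    expanded = pd.concat(out, ignore_index=True)
    return ParticleTable(expanded, symmetry_order=order, columns=cols)


@dataclass
class SortResult:
    sets: dict                 # label -> DataFrame of original particle rows
    fractions: pd.DataFrame    # (pattern, count, fraction)
    n_particles: int
    excluded: pd.DataFrame     # particles with inconsistent row counts

    def fraction(self, label: str) -> float:
        row = self.fractions[self.fractions["pattern"] == label]
        return float(row["fraction"].iloc[0]) if len(row) else 0.0


def sort_particles(table: ParticleTable, classmap: ClassMap) -> SortResult:
    """Group expanded rows per particle, classify and de-duplicate.

    Each original particle's subunit rows (ordered by subunit index,
    i.e. by rotational pose around the ring) are mapped through the
    class map to bound flags, canonicalized under cyclic rotation, and
    the particle is emitted once (its subunit-0 row) into the set for
    its pattern.  Particles with a row count other than the symmetry
    order are excluded and reported.
    """
    S = table.symmetry_order
    cls_col = table.columns["class"]
    if cls_col not in table.df.columns:
        raise ValueError(f"missing class column {cls_col!r}")
    sets: dict[str, list] = {}
    excluded_ids = []
    grouped = table.df.sort_values("subunit_index").groupby(
        "original_particle_id", sort=False)
    for pid, sub in grouped:
        if len(sub) != S:
            excluded_ids.append(pid)
            continue
        flags = [classmap.is_bound(int(c)) for c in sub[cls_col]]
        pattern = classify_pattern(flags, order=S)
        sets.setdefault(pattern.label, []).append(sub.iloc[0])
    out_sets = {label: pd.DataFrame(rows) for label, rows in sets.items()}
    n_ok = sum(len(v) for v in out_sets.values())
    frac_rows = [{"pattern": label, "count": len(v),
                  "fraction": len(v) / n_ok if n_ok else np.nan}
                 for label, v in sorted(out_sets.items())]
    fractions = pd.DataFrame(frac_rows)
    excluded = table.df[table.df["original_particle_id"].isin(excluded_ids)]
    return SortResult(sets=out_sets, fractions=fractions,
                      n_particles=n_ok, excluded=excluded)


def write_pattern_stars(result: SortResult, out_dir,
                        prefix: str = "particles") -> dict:
    """One STAR file of original particles per non-empty pattern.

    Also writes ``summary.csv`` with (pattern, count, fraction).
    Returns {label: path}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, df in result.sets.items():
        if df.empty:
            continue
        safe = label.replace("@", "_at_").replace("(", "").replace(")", "") \
                    .replace(",", "-").replace(" ", "")
        p = out_dir / f"{prefix}_{safe}.star"
        write_star(df, p)
        paths[label] = p
    result.fractions.to_csv(out_dir / "summary.csv", index=False)
    return paths
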