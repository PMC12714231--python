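"""File formats: multi-page TIFF stacks, CSV tables, FASTA precursors.

Table headers follow the documented conventions: object tables carry
``object_id,row,col,area,weight,mean_ch0,mean_ch1,...``; ground-truth and
cell tables ``cell_id,row,col,axial_fraction,true_class,cluster_id`` and
``fish_id,group,subtype,quarter,count``; gut frames
``fish_id,start_row,start_col,end_row,end_col``.  Precursor variants and
regions ride in sidecar TSVs next to the FASTA; peptide modifications are
encoded ``pos|name[;pos|name...]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from eecquant.atlas import MODIFICATION_MASS, PeptideHit, Precursor, PrecursorAtlas
from eecquant.detection import DetectedObject


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (channels, rows, cols) stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_image_stack(path) -> np.ndarray:
    """Read a TIFF into a (channels, rows, cols) float array."""
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return data


def write_objects_csv(path, objects: list[DetectedObject]) -> None:
    rows = []
    for o in objects:
        row = {
            "object_id": o.object_id,
            "row": o.centroid[0],
            "col": o.centroid[1],
            "area": o.area,
            "weight": o.weight,
        }
        for i, m in enumerate(o.mean_intensity):
            row[f"mean_ch{i}"] = m
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_objects_csv(path) -> list[DetectedObject]:
    df = pd.read_csv(path)
    mean_cols = sorted(
        (c for c in df.columns if c.startswith("mean_ch")),
        key=lambda c: int(c.removeprefix("mean_ch")),
    )
    return [
        DetectedObject(
            object_id=int(r.object_id),
            centroid=(float(r.row), float(r.col)),
            area=int(r.area),
            mean_intensity=tuple(float(getattr(r, c)) for c in mean_cols),
            weight=int(getattr(r, "weight", 1)),
        )
        for r in df.itertuples()
    ]


def read_manual_counts_csv(path, fish_id: str | None = None) -> pd.DataFrame:
    """Read a Cell Counter-style manual count export.

    Expects ``Type, X, Y`` columns (``Slice`` optional) as exported by the
    ImageJ Cell Counter plugin; returns a cell table with 0-based
    ``row``/``col`` pixel coordinates, a ``counter_type`` label, and unit
    weights, ready for the spatial stage.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    out = pd.DataFrame(
        {
            "cell_id": np.arange(len(df)),
            "row": df[cols["y"]].astype(float),
            "col": df[cols["x"]].astype(float),
            "counter_type": df[cols["type"]] if "type" in cols else 0,
            "weight": 1,
        }
    )
    if "slice" in cols:
        out["slice"] = df[cols["slice"]]
    if fish_id is not None:
        out.insert(0, "fish_id", fish_id)
    return out


def read_gut_frames_csv(path) -> dict[str, "GutFrame"]:
    from eecquant.gut_axis import GutFrame

    df = pd.read_csv(path)
    return {
        str(r.fish_id): GutFrame(
            start=(float(r.start_row), float(r.start_col)),
            end=(float(r.end_row), float(r.end_col)),
        )
        for r in df.itertuples()
    }


def read_precursors(fasta_path, variants_tsv=None, regions_tsv=None) -> dict[str, Precursor]:
    """Load precursors from FASTA plus optional variant/region sidecars.

    Sidecar headers: ``precursor_id,pos,ref,alt`` and
    ``precursor_id,region_name,start,end`` (tab-separated).
    """
    variants: dict[str, list] = {}
    if variants_tsv is not None:
        for r in pd.read_csv(variants_tsv, sep="\t").itertuples():
            variants.setdefault(str(r.precursor_id), []).append(
                (int(r.pos), str(r.ref), str(r.alt))
            )
    regions: dict[str, list] = {}
    if regions_tsv is not None:
        for r in pd.read_csv(regions_tsv, sep="\t").itertuples():
            regions.setdefault(str(r.precursor_id), []).append(
                (str(r.region_name), int(r.start), int(r.end))
            )
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out[rec.id] = Precursor(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            variants=variants.get(rec.id, []),
            regions=regions.get(rec.id, []),
        )
    return out


def parse_modifications(text: str) -> list[tuple[int, str, float | None]]:
    """Parse ``pos|name[;pos|name...]`` modification annotations.

    ``name`` may be a supported modification name or a numeric delta.
    """
    mods: list[tuple[int, str, float | None]] = []
    if not text or (isinstance(text, float) and np.isnan(text)):
        return mods
    for token in str(text).split(";"):
        pos_s, name = token.split("|", 1)
        name = name.strip()
        try:
            delta: float | None = float(name)
        except ValueError:
            delta = MODIFICATION_MASS.get(name)
            if delta is None:
                raise ValueError(f"unknown modification {name!r}") from None
        mods.append((int(pos_s), name, delta))
    return mods


def read_peptides_tsv(path) -> list[PeptideHit]:
    """Read identified peptides: ``precursor_id, sequence, mods`` TSV."""
    df = pd.read_csv(path, sep="\t")
    hits = []
    for r in df.itertuples():
        mods = parse_modifications(getattr(r, "mods", "") or "")
        hits.append(
            PeptideHit(
                sequence=str(r.sequence),
                modifications=[(p, n, d) for p, n, d in mods],
                precursor_id=str(r.precursor_id),
            )
        )
    return hits


def write_atlas(outdir, atlas: PrecursorAtlas) -> None:
    """Write an atlas as TSV tracks plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = atlas.precursor.id
    pd.DataFrame(
        {
            "position": np.arange(1, len(atlas.precursor) + 1),
            "residue": list(atlas.precursor.sequence),
            "coverage": atlas.coverage,
        }
    ).to_csv(outdir / f"{pid}.coverage.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sequence": h.sequence,
                "start": h.alignment[0],
                "end": h.alignment[1],
                "mods": ";".join(f"{p}|{n}" for p, n, _ in h.modifications),
                "mass": h.mass,
                "regions": ",".join(atlas.region_overlaps[i]),
            }
            for i, h in enumerate(atlas.hits)
        ]
    ).to_csv(outdir / f"{pid}.peptides.tsv", sep="\t", index=False)
    summary = {
        "precursor_id": pid,
        "length": len(atlas.precursor),
        "n_peptides": len(atlas.hits),
        "covered_residues": int((atlas.coverage > 0).sum()),
        "max_depth": int(atlas.coverage.max()) if len(atlas.coverage) else 0,
        "junctions": atlas.junctions,
        "dibasic_sites": [list(s) for s in atlas.dibasic_sites],
    }
    (outdir / f"{pid}.summary.json").write_text(json.dumps(summary, indent=2))
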