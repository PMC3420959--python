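"""File formats: BED-like site tables, JSON sidecars, melt-curve tables
(long TSV / wide CSV), plate maps, calls/groups tables and cohort JSONL.

Every JSON artifact carries a ``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import OffTargetHit, RvdArray, TalenSite
from .melt import AllelePool, MeltCurve

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# sites


def sites_to_bed(sites: Sequence[TalenSite], chrom: str) -> pd.DataFrame:
    """BED6-like table of site spans (one row per site)."""
    rows = [
        {
            "chrom": chrom,
            "start": s.span[0],
            "end": s.span[1],
            "name": f"site_{i + 1}",
            "score": s.rank_score,
            "strand": "+",
        }
        for i, s in enumerate(sites)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_sites_bed(sites: Sequence[TalenSite], chrom: str, path: str | Path) -> None:
    sites_to_bed(sites, chrom).to_csv(path, sep="\t", header=False, index=False)


def site_to_dict(
    site: TalenSite, arrays: tuple[RvdArray, RvdArray] | None = None
) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "span": list(site.span),
        "spacer_len": site.spacer_len,
        "rank_score": site.rank_score,
        "left": {
            "strand": site.left.strand,
            "start": site.left.start,
            "end": site.left.end,
            "anchor_T_pos": site.left.anchor_T_pos,
            "bases": site.left.bases,
        },
        "right": {
            "strand": site.right.strand,
            "start": site.right.start,
            "end": site.right.end,
            "anchor_T_pos": site.right.anchor_T_pos,
            "bases": site.right.bases,
        },
    }
    if arrays is not None:
        d["rvd_left"] = ",".join(arrays[0].codes)
        d["rvd_right"] = ",".join(arrays[1].codes)
    return d


def write_sites_json(
    sites: Sequence[TalenSite],
    path: str | Path,
    arrays: Sequence[tuple[RvdArray, RvdArray]] | None = None,
) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "sites": [
            site_to_dict(s, arrays[i] if arrays is not None else None)
            for i, s in enumerate(sites)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def site_from_dict(d: dict) -> TalenSite:
    from .design import HalfSiteMatch

    def half(h: dict) -> HalfSiteMatch:
        return HalfSiteMatch(
            strand=h["strand"],
            start=h["start"],
            end=h["end"],
            anchor_T_pos=h["anchor_T_pos"],
            bases=h["bases"],
        )

    return TalenSite(
        left=half(d["left"]),
        right=half(d["right"]),
        spacer_len=d["spacer_len"],
        span=tuple(d["span"]),
        rank_score=d["rank_score"],
    )


def read_sites_json(path: str | Path) -> list[TalenSite]:
    payload = json.loads(Path(path).read_text())
    return [site_from_dict(d) for d in payload["sites"]]


def write_offtargets_tsv(hits: Iterable[OffTargetHit], path: str | Path) -> None:
    pd.DataFrame([vars(h) for h in hits]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# melt curves


def curves_to_long(curves: Sequence[MeltCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "temperature": c.temps,
                "fluorescence": c.fluor,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def write_curves_tsv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    """Long-format TSV: sample_id, temperature, fluorescence."""
    curves_to_long(curves).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_curves_csv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    """Wide-format CSV: rows = temperatures, one column per sample."""
    wide = pd.DataFrame(
        {c.sample_id: c.fluor for c in curves}, index=curves[0].temps
    )
    wide.index.name = "temperature"
    wide.to_csv(path, float_format="%.6g")


def read_curves(path: str | Path) -> list[MeltCurve]:
    """Read melt curves from long TSV or wide CSV (detected by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        wide = pd.read_csv(path, index_col=0)
        temps = wide.index.to_numpy(dtype=float)
        return [
            MeltCurve(temps=temps, fluor=wide[c].to_numpy(dtype=float), sample_id=str(c))
            for c in wide.columns
        ]
    long = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in long.groupby("sample_id", sort=False):
        out.append(
            MeltCurve(
                temps=grp["temperature"].to_numpy(dtype=float),
                fluor=grp["fluorescence"].to_numpy(dtype=float),
                sample_id=str(sid),
            )
        )
    return out


def read_platemap(path: str | Path) -> dict[str, str]:
    """Plate map TSV (sample_id, role) with roles wt_ref / unknown."""
    df = pd.read_csv(path, sep="\t")
    roles = dict(zip(df["sample_id"].astype(str), df["role"].astype(str)))
    bad = set(roles.values()) - {"wt_ref", "unknown"}
    if bad:
        raise ValueError(f"unknown plate-map roles: {sorted(bad)}")
    return roles


def write_platemap(roles: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(roles), "role": list(roles.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pools


def write_pool_json(pool: AllelePool, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "alleles": {lab: seq for lab, seq in pool.alleles},
        "freqs": {lab: f for lab, f in zip(pool.labels, pool.freqs)},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_pool_json(path: str | Path) -> AllelePool:
    payload = json.loads(Path(path).read_text())
    return AllelePool.from_dict(payload["alleles"], payload["freqs"])


# ---------------------------------------------------------------------------
# cohort records


def write_jsonl(records: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
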