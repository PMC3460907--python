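"""Embedded single-file store, annotation vocabularies and batch pipeline.

A desk-scale replacement for a database server: one SQLite file holds the
embryo records (with controlled-vocabulary annotations), the mask
parameters and orientation used per embryo (provenance), the extracted
profiles and the fitted boundaries.  ``run_pipeline`` drives the whole
mask -> orient -> profile chain over a batch of image sets, logging
per-embryo failures without aborting the batch; ``export_tables`` writes
the boundary, median and space-time tables as CSV plus SVG/PDF plots.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .aggregate import TimeClass, spacetime_table, variability_dataset
from .boundaries import BoundarySpline, fit_boundary
from .errors import FlyStripError
from .orientation import orient_embryo
from .profiles import extract_from_oriented
from .segmentation import SegmentationParams, make_mask

__all__ = [
    "VOCABULARIES",
    "EmbryoRecord",
    "validate_annotation",
    "EmbryoStore",
    "PipelineConfig",
    "run_pipeline",
    "export_tables",
]

#: Controlled vocabularies for embryo annotation.
VOCABULARIES = {
    "orientation": ("lateral", "nearly lateral", "not lateral"),
    "phase": ("interphase", "mitosis", "unknown"),
    "morphology": ("amnion/serosa present", "bad", "banana", "fat", "good", "ugly"),
    "mask_quality": ("good", "ok", "not good"),
    "staining": ("normal", "weak", "saturated"),
}


@dataclass
class EmbryoRecord:
    """Annotation record for one embryo."""

    embryo_id: str
    brightfield_path: str = ""
    dic_path: str = ""
    nuclear_path: str = ""
    membrane_path: str = ""
    genotype: str = "wild-type"
    orientation: str = "lateral"
    phase: str = "unknown"
    knockdown: str | None = None
    morphology: str = "good"
    mask_quality: str = "good"
    staining: str = "normal"
    stain_colours: dict[str, str] = field(default_factory=dict)  # gene -> colour
    time_class: str | None = None
    comments: str = ""


def validate_annotation(record: EmbryoRecord) -> list[str]:
    """Check every controlled-vocabulary field; return the violations.

    An empty list means the record is valid.  Time classes are validated
    against the cleavage-cycle staging scheme (subdivisions only in C14A).
    """
    violations = []
    for fieldname, vocab in VOCABULARIES.items():
        value = getattr(record, fieldname)
        if value not in vocab:
            violations.append(f"{fieldname}: {value!r} not in {vocab}")
    if record.time_class is not None:
        try:
            TimeClass.parse(record.time_class)
        except Exception as exc:
            violations.append(f"time_class: {exc}")
    return violations


_SCHEMA = """
CREATE TABLE IF NOT EXISTS embryos (
    embryo_id TEXT PRIMARY KEY,
    brightfield_path TEXT, dic_path TEXT, nuclear_path TEXT, membrane_path TEXT,
    genotype TEXT, orientation TEXT, phase TEXT, knockdown TEXT,
    morphology TEXT, mask_quality TEXT, staining TEXT,
    stain_colours TEXT, time_class TEXT, comments TEXT
);
CREATE TABLE IF NOT EXISTS masks (
    embryo_id TEXT PRIMARY KEY,
    gamma REAL, beta REAL, edge_threshold INTEGER, blur_sigma REAL,
    blur_accuracy REAL, post_blur_threshold INTEGER,
    angle REAL, hflip INTEGER, vflip INTEGER,
    crop_row0 INTEGER, crop_col0 INTEGER, crop_height INTEGER, crop_width INTEGER,
    quality TEXT, warnings TEXT, mask_path TEXT
);
CREATE TABLE IF NOT EXISTS profiles (
    embryo_id TEXT, position_percent REAL,
    red REAL, green REAL, blue REAL
);
CREATE INDEX IF NOT EXISTS idx_profiles ON profiles (embryo_id);
CREATE TABLE IF NOT EXISTS boundaries (
    embryo_id TEXT, gene TEXT, channel TEXT, slope_id INTEGER, polarity TEXT,
    x0 REAL, y0 REAL, x1 REAL, y1 REAL, x2 REAL, y2 REAL,
    PRIMARY KEY (embryo_id, gene, channel, slope_id, polarity)
);
CREATE TABLE IF NOT EXISTS log (
    embryo_id TEXT, stage TEXT, status TEXT, message TEXT
);
"""


class EmbryoStore:
    """SQLite-backed store for records, parameters, profiles and boundaries."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self):
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- embryo records -------------------------------------------------
    def put_record(self, record: EmbryoRecord):
        self._conn.execute(
            "INSERT OR REPLACE INTO embryos VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                record.embryo_id,
                record.brightfield_path,
                record.dic_path,
                record.nuclear_path,
                record.membrane_path,
                record.genotype,
                record.orientation,
                record.phase,
                record.knockdown,
                record.morphology,
                record.mask_quality,
                record.staining,
                json.dumps(record.stain_colours),
                record.time_class,
                record.comments,
            ),
        )
        self._conn.commit()

    def get_record(self, embryo_id: str) -> EmbryoRecord | None:
        row = self._conn.execute(
            "SELECT * FROM embryos WHERE embryo_id = ?", (embryo_id,)
        ).fetchone()
        if row is None:
            return None
        keys = [
            "embryo_id",
            "brightfield_path",
            "dic_path",
            "nuclear_path",
            "membrane_path",
            "genotype",
            "orientation",
            "phase",
            "knockdown",
            "morphology",
            "mask_quality",
            "staining",
            "stain_colours",
            "time_class",
            "comments",
        ]
        data = dict(zip(keys, row))
        data["stain_colours"] = json.loads(data["stain_colours"] or "{}")
        return EmbryoRecord(**data)

    def embryo_ids(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT embryo_id FROM embryos ORDER BY embryo_id")]

    # -- masks / provenance ---------------------------------------------
    def put_mask_info(
        self,
        embryo_id: str,
        params: SegmentationParams,
        angle: float,
        hflip: bool,
        vflip: bool,
        crop_box: tuple[int, int, int, int],
        quality: str,
        warnings: list[str],
        mask_path: str = "",
    ):
        self._conn.execute(
            "INSERT OR REPLACE INTO masks VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                embryo_id,
                params.gamma,
                params.beta,
                params.edge_threshold,
                params.blur_sigma,
                params.blur_accuracy,
                params.post_blur_threshold,
                angle,
                int(hflip),
                int(vflip),
                *crop_box,
                quality,
                json.dumps(warnings),
                mask_path,
            ),
        )
        self._conn.commit()

    def get_mask_info(self, embryo_id: str) -> dict | None:
        cur = self._conn.execute("SELECT * FROM masks WHERE embryo_id = ?", (embryo_id,))
        row = cur.fetchone()
        if row is None:
            return None
        keys = [d[0] for d in cur.description]
        info = dict(zip(keys, row))
        info["warnings"] = json.loads(info["warnings"] or "[]")
        info["hflip"], info["vflip"] = bool(info["hflip"]), bool(info["vflip"])
        return info

    # -- profiles --------------------------------------------------------
    def put_profile(self, embryo_id: str, frame: pd.DataFrame):
        self._conn.execute("DELETE FROM profiles WHERE embryo_id = ?", (embryo_id,))
        self._conn.executemany(
            "INSERT INTO profiles VALUES (?,?,?,?,?)",
            [
                (embryo_id, float(p), float(r), float(g), float(b))
                for p, r, g, b in zip(
                    frame["position_percent"], frame["red"], frame["green"], frame["blue"]
                )
            ],
        )
        self._conn.commit()

    def get_profile(self, embryo_id: str) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT position_percent, red, green, blue FROM profiles "
            "WHERE embryo_id = ? ORDER BY position_percent",
            self._conn,
            params=(embryo_id,),
        )

    # -- boundaries ------------------------------------------------------
    def put_boundary(self, embryo_id: str, b: BoundarySpline):
        self._conn.execute(
            "INSERT OR REPLACE INTO boundaries VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (
                embryo_id,
                b.gene,
                b.channel,
                b.slope_id,
                b.polarity,
                *b.knots[0],
                *b.knots[1],
                *b.knots[2],
            ),
        )
        self._conn.commit()

    def boundaries_frame(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT b.*, e.time_class FROM boundaries b "
            "LEFT JOIN embryos e USING (embryo_id)",
            self._conn,
        )

    def iter_boundaries(self):
        """Yield (BoundarySpline, TimeClass) pairs for all stored boundaries."""
        for _, row in self.boundaries_frame().iterrows():
            spline = BoundarySpline(
                gene=row["gene"],
                slope_id=int(row["slope_id"]),
                polarity=row["polarity"],
                channel=row["channel"],
                knots=np.array(
                    [
                        [row["x0"], row["y0"]],
                        [row["x1"], row["y1"]],
                        [row["x2"], row["y2"]],
                    ]
                ),
            )
            tc = TimeClass.parse(row["time_class"]) if row["time_class"] else None
            yield spline, tc

    # -- logging ---------------------------------------------------------
    def log(self, embryo_id: str, stage: str, status: str, message: str = ""):
        self._conn.execute(
            "INSERT INTO log VALUES (?,?,?,?)", (embryo_id, stage, status, message)
        )
        self._conn.commit()

    def log_frame(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM log", self._conn)


@dataclass
class PipelineConfig:
    """Configuration of a batch run.

    ``flips`` maps embryo_id to (hflip, vflip); embryos not listed are not
    flipped.  ``proc_dir`` receives the mask, intermediates and oriented
    images as PNG.
    """

    params: SegmentationParams = field(default_factory=SegmentationParams)
    proc_dir: str | Path | None = None
    flips: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    save_intermediates: bool = False


def _load_rgb(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    if img.shape[2] == 4:
        img = img[..., :3]
    return img


def run_pipeline(
    config: PipelineConfig, image_sets: list[dict], store: EmbryoStore
) -> dict[str, str]:
    """Mask, orient and profile a batch of embryos.

    ``image_sets`` is a list of dicts with keys ``embryo_id``,
    ``dic`` (path, required) and optionally ``brightfield``, ``nuclear``,
    ``membrane``.  Each embryo is processed independently; a failure is
    logged and the batch continues.  Returns {embryo_id: status}, where
    status is 'ok' or the error message.
    """
    statuses: dict[str, str] = {}
    proc_dir = Path(config.proc_dir) if config.proc_dir else None
    if proc_dir:
        proc_dir.mkdir(parents=True, exist_ok=True)
    for entry in image_sets:
        embryo_id = entry["embryo_id"]
        try:
            dic = _load_rgb(entry["dic"])
            bf = _load_rgb(entry["brightfield"]) if entry.get("brightfield") else None
            if bf is None:
                # bright-field missing: profiles are extracted from the DIC
                # image instead (more failure-prone, but supported)
                bf = dic
                store.log(embryo_id, "load", "warning", "no bright-field image; using DIC")
            em = make_mask(dic, config.params)
            hflip, vflip = config.flips.get(embryo_id, (False, False))
            mask, (bf_o,), ores = orient_embryo(em.mask, [bf], hflip=hflip, vflip=vflip)
            profile, strip, spline = extract_from_oriented(mask, bf_o)
            mask_path = ""
            if proc_dir:
                mask_path = str(proc_dir / f"{embryo_id}_mask.png")
                iio.imwrite(mask_path, mask)
                if config.save_intermediates:
                    for stage, img in em.intermediates.items():
                        iio.imwrite(
                            proc_dir / f"{embryo_id}_{stage}.png",
                            np.rint(np.asarray(img, dtype=float)).clip(0, 255).astype(np.uint8),
                        )
            record = store.get_record(embryo_id) or EmbryoRecord(embryo_id=embryo_id)
            record.dic_path = str(entry["dic"])
            record.brightfield_path = str(entry.get("brightfield") or "")
            record.nuclear_path = str(entry.get("nuclear") or "")
            record.membrane_path = str(entry.get("membrane") or "")
            record.mask_quality = em.quality
            store.put_record(record)
            store.put_mask_info(
                embryo_id,
                config.params,
                ores.angle,
                hflip,
                vflip,
                ores.crop_box,
                em.quality,
                em.warnings,
                mask_path,
            )
            store.put_profile(embryo_id, profile.to_frame())
            store.log(embryo_id, "pipeline", "ok")
            statuses[embryo_id] = "ok"
        except Exception as exc:  # per-embryo failure must not abort the batch
            store.log(embryo_id, "pipeline", "error", str(exc))
            statuses[embryo_id] = str(exc)
    return statuses


def fit_boundaries_from_table(store: EmbryoStore, windows: pd.DataFrame) -> int:
    """Fit and store boundary splines from a boundary-window table.

    ``windows`` columns: embryo_id, gene, channel, slope_id, polarity,
    x0_percent, x2_percent.  The signal channel is chosen from the stain
    channel ('purple' -> NBT signal, 'red' -> FastRed signal).  Returns the
    number of boundaries stored.
    """
    from .profiles import ExpressionProfile, stain_signal

    n = 0
    for _, row in windows.iterrows():
        frame = store.get_profile(row["embryo_id"])
        if frame.empty:
            raise FlyStripError(f"no profile stored for embryo {row['embryo_id']}")
        profile = ExpressionProfile(
            positions=frame["position_percent"].to_numpy(),
            red=frame["red"].to_numpy(),
            green=frame["green"].to_numpy(),
            blue=frame["blue"].to_numpy(),
        )
        stain = "NBT_BCIP" if row["channel"] == "purple" else "FastRed"
        signal = stain_signal(profile, stain)
        b = fit_boundary(
            profile.positions,
            signal,
            float(row["x0_percent"]),
            float(row["x2_percent"]),
            gene=row["gene"],
            slope_id=int(row["slope_id"]),
            polarity=row["polarity"],
            channel=row["channel"],
        )
        store.put_boundary(row["embryo_id"], b)
        n += 1
    return n


def _plot_variability(dataset: dict, path_base: Path):
    fig, ax = plt.subplots(figsize=(7, 4))
    for group in dataset["groups"]:
        for x, y in group["curves"]:
            ax.plot(x, y, color=group["color"], alpha=0.35, lw=0.8)
        if group["median"] is not None:
            x, y = group["median"]
            ax.plot(x, y, color=group["color"], lw=2.0,
                    label=f"{group['gene']} {group['time_class']} (n={group['n']})")
    ax.set_xlabel("A-P position (% egg length)")
    ax.set_ylabel("normalised signal intensity")
    if dataset["groups"]:
        ax.legend(fontsize=7)
    for ext in ("svg", "pdf"):
        fig.savefig(path_base.with_suffix(f".{ext}"))
    plt.close(fig)


def _plot_spacetime(table: pd.DataFrame, path_base: Path):
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(table):
        order = sorted(table["time_class"].unique(), key=lambda t: TimeClass.parse(t).sort_key())
        ticks = {t: i for i, t in enumerate(order)}
        for (gene, slope_id, pol), sub in table.groupby(["gene", "slope_id", "polarity"]):
            y = [ticks[t] for t in sub["time_class"]]
            ax.plot(sub["x1_percent"], y, "o-", label=f"{gene} s{slope_id} {pol}", ms=3)
        ax.set_yticks(range(len(order)), order)
        ax.invert_yaxis()  # developmental time flows downwards
        ax.legend(fontsize=7)
    ax.set_xlabel("A-P position (% egg length)")
    ax.set_ylabel("time class")
    for ext in ("svg", "pdf"):
        fig.savefig(path_base.with_suffix(f".{ext}"))
    plt.close(fig)


def export_tables(
    store: EmbryoStore,
    out_dir: str | Path,
    genes: list[str] | None = None,
    time_classes: list[TimeClass] | None = None,
    mode: str = "slopes_and_medians",
) -> dict[str, Path]:
    """Write boundary, median and space-time CSVs plus SVG/PDF plots.

    An empty selection produces header-only CSV files.  Returns the paths
    of the written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_bounds = [(b, tc) for b, tc in store.iter_boundaries() if tc is not None]
    if genes is None:
        genes = sorted({b.gene for b, _ in all_bounds})

    bframe = store.boundaries_frame()
    if genes:
        bframe = bframe[bframe["gene"].isin(genes)]
    if time_classes is not None:
        keep = {str(t) for t in time_classes}
        bframe = bframe[bframe["time_class"].isin(keep)]
    paths = {"boundaries": out_dir / "boundaries.csv"}
    bframe.to_csv(paths["boundaries"], index=False)

    st = spacetime_table(all_bounds, genes=genes or None)
    if time_classes is not None:
        st = st[st["time_class"].isin({str(t) for t in time_classes})]
    paths["spacetime"] = out_dir / "spacetime.csv"
    st.to_csv(paths["spacetime"], index=False)

    dataset = variability_dataset(
        all_bounds, genes=genes, time_classes=time_classes, mode=mode
    )
    med_rows = [
        {
            "gene": g["gene"],
            "slope_id": g["slope_id"],
            "polarity": g["polarity"],
            "time_class": g["time_class"],
            "n": g["n"],
        }
        for g in dataset["groups"]
    ]
    med = pd.DataFrame(med_rows, columns=["gene", "slope_id", "polarity", "time_class", "n"])
    if len(med):
        med = med.merge(st, on=["gene", "slope_id", "polarity", "time_class", "n"], how="left")
    else:
        med["x1_percent"] = pd.Series(dtype=float)
    paths["medians"] = out_dir / "medians.csv"
    med.to_csv(paths["medians"], index=False)

    _plot_variability(dataset, out_dir / "variability")
    _plot_spacetime(st, out_dir / "spacetime")
    paths["variability_plot"] = out_dir / "variability.svg"
    paths["spacetime_plot"] = out_dir / "spacetime.svg"
    return paths
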