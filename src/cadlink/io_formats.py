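"""Readers and writers for the pipeline's exchange formats.

* mzML — only the chromatogram list is consumed (spectra are handled by
  the upstream feature extractor).  The converter dialect encodes the
  detectors as ``BasePeak_0`` (BPI), ``PDA.1$TotalAbsorbance_0`` (PDA) and
  ``UV.1$CAD_1_0`` (CAD); both ``$`` and ``_`` spellings of the separator
  are accepted.  Times are normalized to minutes on read.  A minimal mzML
  writer exists for fixtures.
* feature / annotation tables — tab-separated canonical (comma via flag);
  XIC points inline as ``t:i;t:i;...``.
* GraphML molecular networks via networkx.
* per-peak report TSV.
"""

from __future__ import annotations

import base64
import logging
import zlib
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .models import (CandidateAnnotation, ChromatogramSet, MsFeature, Trace)
from .reporting import ReportRow

__all__ = [
    "DEFAULT_DIALECT",
    "read_multidetector_mzml",
    "write_fixture_mzml",
    "read_feature_table",
    "write_feature_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_network",
    "write_network",
    "write_peak_report",
    "read_peak_report",
]

log = logging.getLogger(__name__)

MZML_NS = "http://psi.hupo.org/ms/mzml"

#: chromatogram-id -> detector label, covering both separator spellings
#: the converter prints.
DEFAULT_DIALECT: dict[str, str] = {
    "BasePeak_0": "BPI_pos",
    "PDA.1$TotalAbsorbance_0": "PDA",
    "PDA.1_TotalAbsorbance_0": "PDA",
    "UV.1$CAD_1_0": "CAD",
    "UV.1_CAD_1_0": "CAD",
}

_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_TIME = "MS:1000595"
_ACC_INTENS = "MS:1000515"
_UNIT_MINUTE = "UO:0000031"
_UNIT_SECOND = "UO:0000010"


def _decode_binary(bda: etree._Element) -> tuple[np.ndarray, Optional[str], Optional[str]]:
    """Decode one binaryDataArray: (values, array-kind accession, unit accession)."""
    dtype = "<f8"
    compressed = False
    kind = unit = None
    for cv in bda.findall(f"{{{MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_ZLIB:
            compressed = True
        elif acc in (_ACC_TIME, _ACC_INTENS):
            kind = acc
            unit = cv.get("unitAccession")
    bin_el = bda.find(f"{{{MZML_NS}}}binary")
    raw = base64.b64decode(bin_el.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float), kind, unit


def read_multidetector_mzml(path: str | Path,
                            dialect: Optional[dict[str, str]] = None) -> ChromatogramSet:
    """Read every recognized chromatogram of an mzML file.

    Chromatogram ids are mapped to detector labels through ``dialect``
    (default :data:`DEFAULT_DIALECT`); unrecognized ids are skipped with a
    warning.  Time arrays are converted to minutes exactly once here,
    using the unit accession (seconds assumed when absent).  A file with
    no CAD chromatogram is still returned; downstream CAD operations
    refuse to run on it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect if dialect is not None else DEFAULT_DIALECT
    tree = etree.parse(str(path))
    traces: dict[str, Trace] = {}
    for chrom in tree.iter(f"{{{MZML_NS}}}chromatogram"):
        cid = chrom.get("id", "")
        detector = dialect.get(cid)
        if detector is None:
            log.warning("ignoring unrecognized chromatogram id %r in %s", cid, path.name)
            continue
        times = intens = None
        for bda in chrom.iter(f"{{{MZML_NS}}}binaryDataArray"):
            vals, kind, unit = _decode_binary(bda)
            if kind == _ACC_TIME:
                times = vals / 60.0 if unit != _UNIT_MINUTE else vals
            elif kind == _ACC_INTENS:
                intens = vals
        if times is None or intens is None:
            log.warning("chromatogram %r lacks time/intensity arrays; skipped", cid)
            continue
        if detector in traces:
            raise ValueError(f"duplicate chromatogram for detector {detector}")
        traces[detector] = Trace(detector_id=detector, times=times, intensities=intens)
    cs = ChromatogramSet(traces=traces, source_path=str(path))
    if not cs.has_cad:
        log.warning("no CAD chromatogram found in %s", path.name)
    return cs


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_fixture_mzml(traces: Iterable[Trace], path: str | Path,
                       dialect: Optional[dict[str, str]] = None,
                       time_unit: str = "minute") -> Path:
    """Write a minimal chromatogram-list mzML (fixture support only).

    Times are written in the requested unit so the reader's unit handling
    can be exercised; 64-bit floats, no compression.
    """
    if time_unit not in ("minute", "second"):
        raise ValueError("time_unit must be 'minute' or 'second'")
    rev = {v: k for k, v in (dialect or DEFAULT_DIALECT).items()}
    root = etree.Element(f"{{{MZML_NS}}}mzML", nsmap={None: MZML_NS}, version="1.1.0")
    run = etree.SubElement(root, f"{{{MZML_NS}}}run", id="run1")
    traces = list(traces)
    clist = etree.SubElement(run, f"{{{MZML_NS}}}chromatogramList", count=str(len(traces)))
    unit_acc = _UNIT_MINUTE if time_unit == "minute" else _UNIT_SECOND
    for i, tr in enumerate(traces):
        cid = rev.get(tr.detector_id, tr.detector_id)
        chrom = etree.SubElement(clist, f"{{{MZML_NS}}}chromatogram", id=cid,
                                 index=str(i), defaultArrayLength=str(len(tr)))
        bdal = etree.SubElement(chrom, f"{{{MZML_NS}}}binaryDataArrayList", count="2")
        times = tr.times if time_unit == "minute" else tr.times * 60.0
        for kind, unit, vals in ((_ACC_TIME, unit_acc, times),
                                 (_ACC_INTENS, None, tr.intensities)):
            payload = _b64(vals)
            bda = etree.SubElement(bdal, f"{{{MZML_NS}}}binaryDataArray",
                                   encodedLength=str(len(payload)))
            for acc, name in ((_ACC_F64, "64-bit float"), (_ACC_NONE, "no compression")):
                etree.SubElement(bda, f"{{{MZML_NS}}}cvParam", cvRef="MS",
                                 accession=acc, name=name)
            attrs = {"cvRef": "MS", "accession": kind,
                     "name": "time array" if kind == _ACC_TIME else "intensity array"}
            if unit is not None:
                attrs.update(unitCvRef="UO", unitAccession=unit, unitName=time_unit)
            etree.SubElement(bda, f"{{{MZML_NS}}}cvParam", **attrs)
            etree.SubElement(bda, f"{{{MZML_NS}}}binary").text = payload
    path = Path(path)
    path.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="utf-8", pretty_print=True))
    return path


# ---------------------------------------------------------------------------
# tabular formats

FEATURE_COLUMNS = ["feature_id", "mode", "mz", "rt_apex", "height", "xic"]
ANNOTATION_COLUMNS = [
    "feature_id", "rank", "structure_id", "molecular_formula", "npc_pathway",
    "npc_superclass", "npc_class", "taxonomic_distance_score", "final_score",
    "closest_organism", "taxon_level",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates a uniqueness rule."""


def _read_table(path: str | Path, required: list[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _encode_xic(tr: Trace) -> str:
    return ";".join(f"{t:.10g}:{i:.10g}" for t, i in zip(tr.times, tr.intensities))


def _decode_xic(s: str) -> Trace:
    pts = [p.split(":") for p in s.split(";") if p]
    t = np.array([float(p[0]) for p in pts])
    y = np.array([float(p[1]) for p in pts])
    return Trace(detector_id="XIC", times=t, intensities=y)


def read_feature_table(path: str | Path, mode: Optional[str] = None,
                       sep: str = "\t") -> list[MsFeature]:
    """Parse an MS feature table (one row per feature, XIC inline).

    Features are returned sorted by retention-time apex.  A duplicated
    feature id or a missing required column raises :class:`SchemaError`.
    """
    df = _read_table(path, FEATURE_COLUMNS, sep)
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise SchemaError(f"duplicate feature_id(s): {dup}")
    feats = []
    for _, row in df.iterrows():
        if mode is not None and row["mode"] != mode:
            continue
        feats.append(MsFeature(
            feature_id=int(row["feature_id"]), mode=row["mode"],
            mz=float(row["mz"]), rt_apex=float(row["rt_apex"]),
            height=float(row["height"]), xic=_decode_xic(row["xic"])))
    feats.sort(key=lambda f: (f.rt_apex, f.feature_id))
    return feats


def write_feature_table(features: Iterable[MsFeature], path: str | Path,
                        sep: str = "\t") -> Path:
    rows = [{"feature_id": f.feature_id, "mode": f.mode, "mz": f"{f.mz:.10g}",
             "rt_apex": f"{f.rt_apex:.10g}", "height": f"{f.height:.10g}",
             "xic": _encode_xic(f.xic)} for f in features]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, sep=sep, index=False)
    return Path(path)


def read_annotation_table(path: str | Path, sep: str = "\t") -> list[CandidateAnnotation]:
    """Parse ranked candidate annotations; rows with unparseable scores are
    rejected with their row index."""
    df = _read_table(path, ANNOTATION_COLUMNS, sep)
    out: list[CandidateAnnotation] = []
    seen: set[tuple[int, int]] = set()
    for idx, row in df.iterrows():
        try:
            fid, rank = int(row["feature_id"]), int(row["rank"])
            tax = float(row["taxonomic_distance_score"])
            score = float(row["final_score"])
        except ValueError as exc:
            raise SchemaError(f"row {idx}: unparseable numeric field ({exc})") from exc
        if (fid, rank) in seen:
            raise SchemaError(f"row {idx}: duplicate rank {rank} for feature {fid}")
        seen.add((fid, rank))
        out.append(CandidateAnnotation(
            feature_id=fid, rank=rank, structure_id=row["structure_id"],
            molecular_formula=row["molecular_formula"], npc_pathway=row["npc_pathway"],
            npc_superclass=row["npc_superclass"], npc_class=row["npc_class"],
            taxonomic_distance_score=tax, final_score=score,
            closest_organism=row["closest_organism"],
            taxon_level=row["taxon_level"] or "none"))
    return out


def write_annotation_table(annotations: Iterable[CandidateAnnotation],
                           path: str | Path, sep: str = "\t") -> Path:
    rows = [{"feature_id": a.feature_id, "rank": a.rank, "structure_id": a.structure_id,
             "molecular_formula": a.molecular_formula, "npc_pathway": a.npc_pathway,
             "npc_superclass": a.npc_superclass, "npc_class": a.npc_class,
             "taxonomic_distance_score": f"{a.taxonomic_distance_score:.10g}",
             "final_score": f"{a.final_score:.10g}",
             "closest_organism": a.closest_organism, "taxon_level": a.taxon_level}
            for a in annotations]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep=sep, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# molecular networks

def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML molecular network with integer-castable node ids."""
    g = nx.read_graphml(path)
    mapping = {n: int(n) for n in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for u, v in g.edges:
        if u not in g.nodes or v not in g.nodes:  # pragma: no cover - nx guards this
            raise ValueError(f"dangling edge ({u}, {v})")
    return g


def write_network(network: nx.Graph, path: str | Path) -> Path:
    for u, v in network.edges:
        if u not in network.nodes or v not in network.nodes:
            raise ValueError(f"dangling edge ({u}, {v})")
    nx.write_graphml(network, path)
    return Path(path)


# ---------------------------------------------------------------------------
# reports

REPORT_COLUMNS = [
    "peak_id", "apex_rt", "area", "area_fraction", "structure_ids",
    "molecular_formulas", "npc_pathways", "npc_superclasses", "npc_classes",
    "taxon_levels", "closest_organisms", "final_scores", "flags",
]


def write_peak_report(rows: Iterable[ReportRow], path: str | Path,
                      sep: str = "\t") -> Path:
    """Write the automated per-peak report (one line per retained CAD peak).

    Multi-candidate fields are pipe-joined within a cell.
    """
    def join(vals):
        return "|".join(str(v) for v in vals)

    recs = []
    for r in rows:
        recs.append({
            "peak_id": r.peak_id,
            "apex_rt": f"{r.apex_rt:.10g}",
            "area": f"{r.area:.10g}",
            "area_fraction": f"{r.area_fraction:.10g}",
            "structure_ids": join(c["structure_id"] for c in r.candidates),
            "molecular_formulas": join(c["molecular_formula"] for c in r.candidates),
            "npc_pathways": join(c["npc_pathway"] for c in r.candidates),
            "npc_superclasses": join(c["npc_superclass"] for c in r.candidates),
            "npc_classes": join(c["npc_class"] for c in r.candidates),
            "taxon_levels": join(c["taxon_level"] for c in r.candidates),
            "closest_organisms": join(c["closest_organism"] for c in r.candidates),
            "final_scores": join(f"{c['final_score']:.10g}" for c in r.candidates),
            "flags": join(r.flags),
        })
    pd.DataFrame(recs, columns=REPORT_COLUMNS).to_csv(path, sep=sep, index=False)
    return Path(path)


def read_peak_report(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a written peak report back as a DataFrame (round-trip checks)."""
    return _read_table(path, REPORT_COLUMNS, sep)
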