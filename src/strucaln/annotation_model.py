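"""The aggregate annotation document and its XML container.

One :class:`AnnotationDocument` holds the alignment with all per-residue
tracks, the per-column track, superposition metadata, the identity table, and
full provenance (tool, version, every threshold used).  Serialization is
lossless at six significant digits for floats; documents carry a
format-version attribute and are validated against the XSD shipped with the
package (``annotation_schema.xsd``).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lxml import etree

from . import __version__
from .config import AnnotationParams
from .errors import AssemblyError, SchemaValidationError
from .types import (AlignedSequence, Alignment, ColumnAnnotation,
                    PredictionTrack, ResidueAnnotation, SuperpositionResult)

FORMAT_VERSION = "1.0"
TOOL_NAME = "strucaln"


@dataclass
class AnnotationDocument:
    alignment: Alignment
    columns: list[ColumnAnnotation]
    superposition: Optional[SuperpositionResult] = None
    pid_table: list[tuple[str, float]] = field(default_factory=list)
    params: AnnotationParams = field(default_factory=AnnotationParams)

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


def build_document(aln: Alignment,
                   residue_tracks: dict[str, list[ResidueAnnotation]],
                   column_track: list[ColumnAnnotation],
                   sup: Optional[SuperpositionResult],
                   pids: list[tuple[str, float]],
                   params: AnnotationParams) -> AnnotationDocument:
    """Assemble and validate the document; every track must cover the same
    alignment."""
    if len(column_track) != aln.n_columns:
        raise AssemblyError(
            f"column track has {len(column_track)} entries, alignment has "
            f"{aln.n_columns} columns")
    for seq in aln.sequences:
        track = residue_tracks.get(seq.seq_id)
        if seq.role in ("structure", "model"):
            if track is None:
                raise AssemblyError(
                    f"missing residue track for structure sequence {seq.seq_id!r}")
        if track is not None:
            if len(track) != len(seq.ungapped):
                raise AssemblyError(
                    f"residue track for {seq.seq_id!r} has {len(track)} "
                    f"entries, sequence has {len(seq.ungapped)} residues")
            seq.residue_annotations = track
    return AnnotationDocument(alignment=aln, columns=column_track,
                              superposition=sup, pid_table=pids, params=params)


# ------------------------------------------------------------- serialization

def _fmt(x: Optional[float]) -> str:
    return format(float(x), ".6g")


def _load_schema() -> etree.XMLSchema:
    data = (importlib.resources.files("strucaln") /
            "annotation_schema.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(data))


def write_xml(doc: AnnotationDocument) -> bytes:
    """Serialize the document as UTF-8 annotation XML."""
    root = etree.Element("alignment-annotation", version=FORMAT_VERSION)
    prov = etree.SubElement(root, "provenance", tool=TOOL_NAME,
                            release=__version__)
    for key, value in doc.params.as_dict().items():
        if isinstance(value, list):
            value = " ".join(_fmt(v) for v in value)
        etree.SubElement(prov, "parameter", name=key, value=str(value))
    aln_el = etree.SubElement(root, "alignment",
                              columns=str(doc.alignment.n_columns))
    for seq in doc.alignment.sequences:
        seq_el = etree.SubElement(aln_el, "sequence", id=seq.seq_id,
                                  role=seq.role)
        etree.SubElement(seq_el, "gapped").text = seq.gapped
        if seq.residue_annotations is not None:
            res_el = etree.SubElement(seq_el, "residues")
            for k, ann in enumerate(seq.residue_annotations, start=1):
                attrs = {"index": str(k), "ss": ann.ss,
                         "buried": _bool(ann.buried),
                         "hb-amide": _bool(ann.hbond_to_amide),
                         "hb-carbonyl": _bool(ann.hbond_to_carbonyl)}
                if ann.rel_sasa is not None:
                    attrs["rel-sasa"] = _fmt(ann.rel_sasa)
                if ann.positive_phi is not None:
                    attrs["positive-phi"] = _bool(ann.positive_phi)
                if ann.depth is not None:
                    attrs["depth"] = _fmt(ann.depth)
                if ann.chain_contact is not None:
                    attrs["chain-contact"] = ann.chain_contact
                if ann.ligand_contact is not None:
                    attrs["ligand-contact"] = ann.ligand_contact
                if ann.contacts:
                    attrs["contacts"] = " ".join(
                        str(c + 1) for c in sorted(ann.contacts))
                etree.SubElement(res_el, "residue", **attrs)
        if seq.prediction is not None:
            pred_el = etree.SubElement(seq_el, "prediction")
            p = seq.prediction
            for k in range(len(p)):
                etree.SubElement(pred_el, "residue", index=str(k + 1),
                                 helix=_fmt(p.helix[k]), strand=_fmt(p.strand[k]),
                                 coil=_fmt(p.coil[k]),
                                 disorder=str(p.disorder[k]))
    cols_el = etree.SubElement(root, "columns")
    for i, c in enumerate(doc.columns, start=1):
        attrs = {"index": str(i), "entropy": _fmt(c.entropy),
                 "entropy-symbol": c.entropy_symbol}
        if c.consensus_ss:
            attrs["consensus-ss"] = c.consensus_ss
        if c.rmsd is not None:
            attrs["rmsd"] = _fmt(c.rmsd)
            attrs["rmsd-bin"] = str(c.rmsd_bin)
        etree.SubElement(cols_el, "column", **attrs)
    if doc.superposition is not None:
        sup = doc.superposition
        sup_el = etree.SubElement(root, "superposition",
                                  iterations=str(sup.n_iterations))
        for sid in sup.ids:
            R = sup.rotations[sid]
            t = sup.translations[sid]
            etree.SubElement(
                sup_el, "transform", id=sid,
                rotation=" ".join(_fmt(v) for v in np.asarray(R).ravel()),
                translation=" ".join(_fmt(v) for v in np.asarray(t)))
        for col in sorted(sup.weights):
            etree.SubElement(sup_el, "weight", column=str(col),
                             value=_fmt(sup.weights[col]))
    if doc.pid_table:
        pid_el = etree.SubElement(root, "pid-table")
        for sid, pid in doc.pid_table:
            etree.SubElement(pid_el, "pid", id=sid, value=_fmt(pid))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str) -> bool:
    return s == "true"


def read_xml(data: bytes) -> AnnotationDocument:
    """Parse and schema-validate annotation XML back into a document."""
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as e:
        raise SchemaValidationError(f"not well-formed XML: {e}") from e
    schema = _load_schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise SchemaValidationError(
            f"schema violation at {err.path or 'document'}: {err.message}")
    params_kwargs = {}
    defaults = AnnotationParams()
    for p in root.find("provenance"):
        name, value = p.get("name"), p.get("value")
        default = getattr(defaults, name, None)
        if default is None and name not in AnnotationParams.__annotations__:
            continue
        if name == "rmsd_bin_edges":
            params_kwargs[name] = tuple(float(v) for v in value.split())
        elif isinstance(default, bool):
            params_kwargs[name] = _parse_bool(value)
        elif isinstance(default, int):
            params_kwargs[name] = int(value)
        elif isinstance(default, float):
            params_kwargs[name] = float(value)
        else:
            params_kwargs[name] = value
    params = AnnotationParams(**params_kwargs)
    aln_el = root.find("alignment")
    sequences = []
    for seq_el in aln_el.findall("sequence"):
        seq = AlignedSequence(seq_id=seq_el.get("id"), role=seq_el.get("role"),
                              gapped=seq_el.find("gapped").text)
        res_el = seq_el.find("residues")
        if res_el is not None:
            track = []
            for r in res_el.findall("residue"):
                contacts = frozenset(int(c) - 1
                                     for c in (r.get("contacts") or "").split())
                pp = r.get("positive-phi")
                track.append(ResidueAnnotation(
                    ss=r.get("ss"),
                    rel_sasa=(None if r.get("rel-sasa") is None
                              else float(r.get("rel-sasa"))),
                    buried=_parse_bool(r.get("buried")),
                    positive_phi=None if pp is None else _parse_bool(pp),
                    hbond_to_amide=_parse_bool(r.get("hb-amide")),
                    hbond_to_carbonyl=_parse_bool(r.get("hb-carbonyl")),
                    depth=(None if r.get("depth") is None
                           else float(r.get("depth"))),
                    chain_contact=r.get("chain-contact"),
                    ligand_contact=r.get("ligand-contact"),
                    contacts=contacts))
            seq.residue_annotations = track
        pred_el = seq_el.find("prediction")
        if pred_el is not None:
            rows = pred_el.findall("residue")
            seq.prediction = PredictionTrack(
                helix=[float(r.get("helix")) for r in rows],
                strand=[float(r.get("strand")) for r in rows],
                coil=[float(r.get("coil")) for r in rows],
                disorder=[int(r.get("disorder")) for r in rows])
        sequences.append(seq)
    aln = Alignment(sequences, max_sequences=params.max_sequences)
    columns = []
    for c in root.find("columns").findall("column"):
        rmsd = c.get("rmsd")
        columns.append(ColumnAnnotation(
            entropy=float(c.get("entropy")),
            entropy_symbol=c.get("entropy-symbol"),
            consensus_ss=c.get("consensus-ss") or "",
            rmsd=None if rmsd is None else float(rmsd),
            rmsd_bin=None if rmsd is None else int(c.get("rmsd-bin"))))
    sup = None
    sup_el = root.find("superposition")
    if sup_el is not None:
        ids, rotations, translations = [], {}, {}
        for tr in sup_el.findall("transform"):
            sid = tr.get("id")
            ids.append(sid)
            rotations[sid] = np.array(
                [float(v) for v in tr.get("rotation").split()]).reshape(3, 3)
            translations[sid] = np.array(
                [float(v) for v in tr.get("translation").split()])
        weights = {int(w.get("column")): float(w.get("value"))
                   for w in sup_el.findall("weight")}
        sup = SuperpositionResult(ids=ids, rotations=rotations,
                                  translations=translations, column_coords={},
                                  weights=weights,
                                  n_iterations=int(sup_el.get("iterations")))
    pids = []
    pid_el = root.find("pid-table")
    if pid_el is not None:
        pids = [(p.get("id"), float(p.get("value")))
                for p in pid_el.findall("pid")]
    return AnnotationDocument(alignment=aln, columns=columns,
                              superposition=sup, pid_table=pids, params=params)
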