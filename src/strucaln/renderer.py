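"""Stand-alone HTML typesetting of an annotation document.

The typesetting key: burial sets the case (uppercase = buried), secondary
structure sets the colour (α red, 3₁₀ maroon, β blue), positive φ renders
italic, a sidechain→mainchain-amide hydrogen bond renders bold and a
sidechain→carbonyl bond underlined; residue depth shades the background in
eight grey levels (darker = deeper); chain contacts draw a coloured bar above
the letter and ligand contacts below; rows without structural annotation are
coloured by the Taylor physicochemical scheme and carry their prediction
bars.  Below each alignment block sit the entropy symbol row (* then 0-9),
the secondary-structure consensus row (a/b/3 on red/blue/orange), and the
per-column RMSD row drawn with five increasing-height block glyphs.

Rendering is a pure function of the document: identical documents yield
byte-identical HTML.  Each glyph carries a ``data-feat`` attribute listing
its features textually (the static stand-in for interactive hover details);
the print variant drops these attributes and the ink-hostile backgrounds.
"""
from __future__ import annotations

import html
from typing import Optional

from .annotation_model import AnnotationDocument
from .config import TAYLOR_COLORS
from .prediction_tracks import disorder_render_class, ss_render_class
from .types import GAP, AlignedSequence, ColumnAnnotation, ResidueAnnotation

RMSD_GLYPHS = ("_", "▂", "▄", "▆", "█")

SS_COLORS = {"H": "#CC0000", "G": "#800000", "E": "#0000CC", "C": "#000000"}
CONSENSUS_BG = {"a": "#CC0000", "b": "#0000CC", "3": "#E07000"}

_PARTNER_PALETTE = ("#2ca02c", "#9467bd", "#8c564b", "#e377c2", "#17becf",
                    "#bcbd22", "#ff7f0e", "#1f77b4")
_N_DEPTH_LEVELS = 8


def feature_string(ann: ResidueAnnotation) -> str:
    """Compact textual listing of all features (the hover-details stand-in);
    parseable back with :func:`parse_feature_string`."""
    parts = [f"ss={ann.ss}",
             f"buried={int(ann.buried)}",
             f"hba={int(ann.hbond_to_amide)}",
             f"hbc={int(ann.hbond_to_carbonyl)}"]
    if ann.rel_sasa is not None:
        parts.append(f"rel={ann.rel_sasa:.1f}")
    if ann.positive_phi is not None:
        parts.append(f"phi+={int(ann.positive_phi)}")
    if ann.depth is not None:
        parts.append(f"depth={ann.depth:.2f}")
    if ann.chain_contact:
        parts.append(f"chain={ann.chain_contact}")
    if ann.ligand_contact:
        parts.append(f"lig={ann.ligand_contact}")
    if ann.contacts:
        parts.append("contacts=" + ",".join(str(c + 1)
                                            for c in sorted(ann.contacts)))
    return ";".join(parts)


def parse_feature_string(s: str) -> dict:
    """Inverse of :func:`feature_string` (values as strings/ints/floats)."""
    out: dict = {}
    for item in s.split(";"):
        key, val = item.split("=", 1)
        if key in ("buried", "hba", "hbc", "phi+"):
            out[key] = bool(int(val))
        elif key in ("rel", "depth"):
            out[key] = float(val)
        elif key == "contacts":
            out[key] = frozenset(int(v) - 1 for v in val.split(","))
        else:
            out[key] = val
    return out


def _depth_range(doc: AnnotationDocument) -> tuple[float, float]:
    depths = [a.depth for s in doc.alignment.sequences
              if s.residue_annotations
              for a in s.residue_annotations if a.depth is not None]
    if not depths:
        return 0.0, 1.0
    lo, hi = min(depths), max(depths)
    return (lo, hi if hi > lo else lo + 1.0)


def _depth_level(depth: float, lo: float, hi: float) -> int:
    frac = (depth - lo) / (hi - lo)
    return min(_N_DEPTH_LEVELS - 1, int(frac * _N_DEPTH_LEVELS))


def _partner_colors(doc: AnnotationDocument) -> dict[str, str]:
    """Stable colour per chain/ligand partner id, in order of appearance."""
    colors: dict[str, str] = {}
    for seq in doc.alignment.sequences:
        if not seq.residue_annotations:
            continue
        for ann in seq.residue_annotations:
            for pid in (ann.chain_contact, ann.ligand_contact):
                if pid and pid not in colors:
                    colors[pid] = _PARTNER_PALETTE[len(colors)
                                                   % len(_PARTNER_PALETTE)]
    return colors


def render_residue(letter: str, annotation: Optional[ResidueAnnotation],
                   role: str, depth_bounds: tuple[float, float] = (0.0, 1.0),
                   partner_colors: Optional[dict[str, str]] = None,
                   prediction_class: str = "none", disordered: bool = False,
                   print_mode: bool = False) -> str:
    """One styled glyph (an HTML <span>) for a residue or gap."""
    if letter == GAP:
        return f'<span class="gap">{GAP}</span>'
    partner_colors = partner_colors or {}
    classes: list[str] = []
    styles: list[str] = []
    if annotation is not None and role in ("structure", "model"):
        display = letter.upper() if annotation.buried else letter.lower()
        classes.append(f"ss-{annotation.ss}")
        if annotation.positive_phi:
            classes.append("pphi")
        if annotation.hbond_to_amide:
            classes.append("hba")
        if annotation.hbond_to_carbonyl:
            classes.append("hbc")
        if annotation.depth is not None and not print_mode:
            classes.append(f"d{_depth_level(annotation.depth, *depth_bounds)}")
        if annotation.chain_contact:
            styles.append("border-top:2px solid "
                          f"{partner_colors.get(annotation.chain_contact, '#444')}")
        if annotation.ligand_contact:
            styles.append("border-bottom:2px solid "
                          f"{partner_colors.get(annotation.ligand_contact, '#444')}")
    else:
        display = letter
        classes.append(f"aa-{letter.upper()}")
        if prediction_class != "none":
            classes.append(f"pred-{prediction_class}")
        if disordered and not print_mode:
            classes.append("disord")
    attrs = f' class="{" ".join(classes)}"' if classes else ""
    if styles:
        attrs += f' style="{";".join(styles)}"'
    if annotation is not None and not print_mode:
        attrs += f' data-feat="{html.escape(feature_string(annotation), quote=True)}"'
    return f"<span{attrs}>{html.escape(display)}</span>"


def _ruler(start: int, end: int) -> str:
    cells = []
    for col in range(start, end + 1):
        if col % 10 == 0:
            label = str(col)
            cells = cells[:-(len(label) - 1)] if len(label) > 1 else cells
            cells.append(label)
        else:
            cells.append(" ")
    return "".join(cells)[-(end - start + 1):]


def render_column_rows(columns: list[ColumnAnnotation], start: int, end: int,
                       with_consensus: bool, with_rmsd: bool) -> list[str]:
    """The annotation rows under one alignment block: entropy symbols, SS
    consensus, RMSD bin glyphs (the latter two only when available)."""
    rows = []
    ent = "".join(html.escape(c.entropy_symbol)
                  for c in columns[start - 1:end])
    rows.append(f'<span class="row-label">entropy</span>{ent}')
    if with_consensus:
        cons = []
        for c in columns[start - 1:end]:
            if c.consensus_ss:
                cons.append(f'<span class="cons-{c.consensus_ss}">'
                            f"{c.consensus_ss}</span>")
            else:
                cons.append(" ")
        rows.append('<span class="row-label">ss cons.</span>' + "".join(cons))
    if with_rmsd:
        glyphs = []
        for c in columns[start - 1:end]:
            if c.rmsd_bin is None:
                glyphs.append(" ")
            else:
                glyphs.append(RMSD_GLYPHS[min(c.rmsd_bin, len(RMSD_GLYPHS) - 1)])
        rows.append('<span class="row-label">rmsd</span>'
                    + html.escape("".join(glyphs)))
    return rows


_FORMAT_KEY = """
<section class="format-key">
<h2>Format key</h2>
<ul>
<li>UPPERCASE: buried (relative accessibility below the burial threshold); lowercase: exposed.</li>
<li>Colour (structure rows): <span class="ss-H">&alpha;-helix</span>,
<span class="ss-G">3<sub>10</sub> helix</span>, <span class="ss-E">&beta;-strand</span>, black coil.</li>
<li><i>Italic</i>: positive mainchain &phi;. <b>Bold</b>: sidechain H-bond to a mainchain amide.
<u>Underline</u>: sidechain H-bond to a mainchain carbonyl.</li>
<li>Grey background: residue depth (darker = deeper).</li>
<li>Bar above: chain contact; bar below: ligand contact (coloured by partner).</li>
<li>Sequence rows: Taylor physicochemical colours; prediction bars above
(dark = confident helix/strand, light = weak); light green background: predicted disorder.</li>
<li>Entropy row: * fully conserved, then 0&ndash;9 over 0.1 intervals.</li>
<li>Consensus row: a/b/3 = &alpha;/&beta;/3<sub>10</sub> at the consensus threshold.</li>
<li>RMSD row: _ &lt;2 &Aring;, &#x2582; &lt;4 &Aring;, &#x2584; &lt;6 &Aring;,
&#x2586; &lt;8 &Aring;, &#x2588; &ge;8 &Aring;.</li>
</ul>
</section>
"""


def _css(doc: AnnotationDocument, print_mode: bool) -> str:
    rules = [
        "body{font-family:sans-serif;margin:1em;}",
        "pre{font-family:'DejaVu Sans Mono',monospace;line-height:1.45;}",
        ".row-label{display:inline-block;width:9ch;color:#666;"
        "font-size:80%;}",
        ".gap{color:#999;}",
        ".pphi{font-style:italic;}",
        ".hba{font-weight:bold;}",
        ".hbc{text-decoration:underline;}",
    ]
    for cls, col in SS_COLORS.items():
        rules.append(f".ss-{cls}{{color:{col};}}")
    for sym, bg in CONSENSUS_BG.items():
        rules.append(f".cons-{sym}{{background:{bg};color:#fff;}}")
    for aa, col in TAYLOR_COLORS.items():
        rules.append(f".aa-{aa}{{color:{col};}}")
    if not print_mode:
        for k in range(_N_DEPTH_LEVELS):
            shade = 255 - int(k * (110 / (_N_DEPTH_LEVELS - 1)))
            rules.append(f".d{k}{{background:rgb({shade},{shade},{shade});}}")
        rules.append(".disord{background:#B8F0B8;}")
    rules += [
        ".pred-strong-helix{border-top:3px solid #990000;}",
        ".pred-weak-helix{border-top:3px solid #E08080;}",
        ".pred-strong-strand{border-top:3px solid #000099;}",
        ".pred-weak-strand{border-top:3px solid #8080E0;}",
        ".format-key{font-size:90%;color:#333;}",
        "table.pid{border-collapse:collapse;}",
        "table.pid td,table.pid th{border:1px solid #999;padding:2px 8px;}",
    ]
    return "\n".join(rules)


def render_document(doc: AnnotationDocument, mode: str = "interactive-lite"
                    ) -> bytes:
    """Render the complete self-contained HTML page (inline CSS, no external
    resources).  ``mode`` is ``interactive-lite`` or ``print``."""
    if mode not in ("interactive-lite", "print"):
        raise ValueError(f"unknown render mode {mode!r}")
    print_mode = mode == "print"
    aln = doc.alignment
    depth_bounds = _depth_range(doc)
    partner_colors = _partner_colors(doc)
    has_structs = any(s.residue_annotations for s in aln.sequences)
    has_rmsd = any(c.rmsd is not None for c in doc.columns)
    wrap = doc.params.wrap_width
    label_w = max(len(s.seq_id) for s in aln.sequences)
    label_w = max(label_w, 9)
    blocks = []
    for start in range(1, aln.n_columns + 1, wrap):
        end = min(start + wrap - 1, aln.n_columns)
        lines = []
        ruler = _ruler(start, end)
        lines.append(f'<span class="row-label"></span>'
                     f'<span class="ruler">{ruler}</span>')
        for seq in aln.sequences:
            glyphs = []
            for col in range(start, end + 1):
                letter = seq.gapped[col - 1]
                ann = None
                pred_class, disord = "none", False
                if letter != GAP:
                    ri = seq.residue_index_at_column(col)
                    if seq.residue_annotations is not None:
                        ann = seq.residue_annotations[ri]
                    if seq.prediction is not None and ri < len(seq.prediction):
                        pred_class = ss_render_class(seq.prediction.helix[ri],
                                                     seq.prediction.strand[ri])
                        disord = disorder_render_class(
                            seq.prediction.disorder[ri],
                            doc.params.disorder_min_conf)
                glyphs.append(render_residue(
                    letter, ann, seq.role, depth_bounds, partner_colors,
                    pred_class, disord, print_mode))
            label = html.escape(f"{seq.seq_id:<{label_w}s}"[:label_w])
            lines.append(f'<span class="row-label seq-label">{label}</span>'
                         f'<span class="seq-row">' + "".join(glyphs)
                         + "</span>")
        for row in render_column_rows(doc.columns, start, end,
                                      with_consensus=has_structs,
                                      with_rmsd=has_rmsd):
            lines.append(f'<span class="annot-row">{row}</span>')
        blocks.append("<pre>" + "\n".join(lines) + "</pre>")
    pid_html = ""
    if doc.pid_table:
        rows = "".join(f"<tr><td>{html.escape(sid)}</td><td>{pid:.1f}</td></tr>"
                       for sid, pid in doc.pid_table)
        pid_html = ('<h2>Percentage sequence identity</h2>'
                    '<table class="pid"><tr><th>structure</th>'
                    '<th>PID (%)</th></tr>' + rows + "</table>")
    body = "\n".join(blocks)
    key = "" if print_mode else _FORMAT_KEY
    html_doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Annotated alignment</title>
<style>
{_css(doc, print_mode)}
</style>
</head>
<body>
<h1>Annotated alignment</h1>
{key}
{body}
{pid_html}
</body>
</html>
"""
    return html_doc.encode("utf-8")


def extract_fasta(doc: AnnotationDocument) -> str:
    """FASTA text of the alignment exactly as held in the document."""
    out = []
    for seq in doc.alignment.sequences:
        out.append(f">{seq.seq_id}")
        g = seq.gapped
        for k in range(0, len(g), 60):
            out.append(g[k:k + 60])
    return "\n".join(out) + "\n"
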