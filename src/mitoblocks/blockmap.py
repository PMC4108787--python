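"""Linearized block-map rendering as Scalable Vector Graphics.

Each genome gets one horizontal track; syntenic-block placements are
drawn as rectangles in two lanes (forward above, reverse below the
axis, mirroring the two-ring convention of circular mitogenome plots),
repeat copies as thin marks under the axis and candidate ORFs as
diamond markers.  The SVG is plain XML built with the standard library,
so tests can parse it back and count glyphs.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

__all__ = ["render_block_map"]

_PALETTE = [
    "#4e79a7", "#f28e2b", "#59a14f", "#e15759", "#76b7b2", "#edc948",
    "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
]

TRACK_H = 90
MARGIN = 60
WIDTH = 1200


def render_block_map(genomes, blocks, repeats, candidates, orf_intervals, path):
    """Write an SVG block map.

    Parameters
    ----------
    genomes : list of GenomeRecord
    blocks : list of SyntenicBlock
    repeats : dict genome_id -> list of RepeatMatch
    candidates : dict genome_id -> list of candidate ORF names
    orf_intervals : dict genome_id -> {orf name: CircularInterval}
    path : output file
    """
    height = MARGIN * 2 + TRACK_H * max(1, len(genomes))
    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(WIDTH),
        height=str(height),
        viewBox=f"0 0 {WIDTH} {height}",
    )
    ET.SubElement(svg, "title").text = "syntenic block map"
    legend = ET.SubElement(svg, "g", attrib={"class": "legend"})
    ET.SubElement(
        legend,
        "text",
        x=str(MARGIN),
        y="24",
        attrib={"font-size": "14", "font-family": "sans-serif"},
    ).text = "Syntenic blocks (two lanes: forward above / reverse below), repeats, candidate ORFs"

    label_color: dict[str, str] = {}
    for b in blocks:
        base = b.label.rstrip("′")
        if base not in label_color:
            label_color[base] = _PALETTE[len(label_color) % len(_PALETTE)]

    for t, genome in enumerate(genomes):
        L = genome.length
        scale = (WIDTH - 2 * MARGIN) / L
        y_axis = MARGIN + TRACK_H * t + TRACK_H // 2
        g = ET.SubElement(svg, "g", attrib={"class": f"track-{genome.id}"})
        ET.SubElement(
            g, "line",
            x1=str(MARGIN), x2=str(WIDTH - MARGIN), y1=str(y_axis), y2=str(y_axis),
            stroke="#333", attrib={"stroke-width": "1"},
        )
        ET.SubElement(
            g, "text", x=str(MARGIN), y=str(y_axis - TRACK_H // 2 + 12),
            attrib={"font-size": "12", "font-family": "sans-serif"},
        ).text = f"{genome.id} ({L:,} bp)"
        for b in blocks:
            for p in b.on(genome.id):
                color = label_color.get(p.label.rstrip("′"), "#999")
                lane_y = y_axis - 22 if p.orientation == "forward" else y_axis + 6
                for s, e in p.interval.segments(L):
                    ET.SubElement(
                        g, "rect",
                        x=f"{MARGIN + s * scale:.1f}", y=str(lane_y),
                        width=f"{max(1.0, (e - s) * scale):.1f}", height="16",
                        fill=color, stroke="#222",
                        attrib={"class": "block", "data-label": p.label},
                    )
                mid = MARGIN + (p.interval.start + p.interval.span / 2) % L * scale
                ET.SubElement(
                    g, "text", x=f"{mid:.1f}", y=str(lane_y - 2),
                    attrib={"font-size": "9", "font-family": "sans-serif",
                            "text-anchor": "middle"},
                ).text = p.label
        for r in repeats.get(genome.id, []):
            for iv in (r.a, r.b):
                for s, e in iv.segments(L):
                    ET.SubElement(
                        g, "rect",
                        x=f"{MARGIN + s * scale:.1f}", y=str(y_axis + 26),
                        width=f"{max(1.0, (e - s) * scale):.1f}", height="5",
                        fill="#7f4f24",
                        attrib={"class": "repeat"},
                    )
        names = candidates.get(genome.id, [])
        intervals = orf_intervals.get(genome.id, {})
        for name in names:
            iv = intervals.get(name)
            if iv is None:
                continue
            x = MARGIN + (iv.start % L) * scale
            ET.SubElement(
                g, "path",
                d=f"M {x:.1f} {y_axis - 34} l 5 7 l -5 7 l -5 -7 z",
                fill="#d62728",
                attrib={"class": "candidate", "data-name": name},
            )
            ET.SubElement(
                g, "text", x=f"{x + 7:.1f}", y=str(y_axis - 26),
                attrib={"font-size": "10", "font-family": "sans-serif",
                        "fill": "#d62728"},
            ).text = name
    tree = ET.ElementTree(svg)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return Path(path)
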