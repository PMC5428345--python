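"""Reading and writing segmentation labels.

Two dialects are supported: a tab-separated table with columns
``start_s  end_s  class`` and a Praat TextGrid with one interval tier
per class (unlabelled stretches are written as empty-text intervals).
"""

from __future__ import annotations

from pathlib import Path

from .intervals import CLASSES, LabeledInterval, SegmentTiers


def write_tsv(path, tiers: SegmentTiers) -> None:
    lines = ["start_s\tend_s\tclass"]
    for iv in tiers.to_flat():
        lines.append(f"{iv.start_s:.6f}\t{iv.end_s:.6f}\t{iv.klass}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path) -> SegmentTiers:
    tiers = SegmentTiers()
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValueError(f"empty label file {path!r}")
    body = text[1:] if text[0].lower().startswith("start") else text
    end = 0.0
    for line in body:
        if not line.strip():
            continue
        s, e, k = line.split("\t")
        iv = LabeledInterval(float(s), float(e), k.strip())
        tiers.tier(iv.klass).append(iv)
        end = max(end, iv.end_s)
    tiers.duration_s = end
    for name in CLASSES:
        tiers.tier(name).sort(key=lambda iv: iv.start_s)
    return tiers


def _escape(s: str) -> str:
    return s.replace('"', '""')


def write_textgrid(path, tiers: SegmentTiers) -> None:
    """Serialize as a full ("long") TextGrid, one interval tier per class."""
    dur = tiers.duration_s
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {dur:.6f}",
        "tiers? <exists>",
        f"size = {len(CLASSES)}",
        "item []:",
    ]
    for t_idx, name in enumerate(CLASSES, start=1):
        ivs = sorted(tiers.tier(name), key=lambda iv: iv.start_s)
        # fill gaps with empty-text intervals so the tier tiles [0, dur]
        filled = []
        t = 0.0
        for iv in ivs:
            if iv.start_s > t + 1e-9:
                filled.append((t, iv.start_s, ""))
            filled.append((iv.start_s, iv.end_s, name))
            t = iv.end_s
        if dur > t + 1e-9 or not filled:
            filled.append((t, dur, ""))
        out += [
            f"    item [{t_idx}]:",
            '        class = "IntervalTier"',
            f'        name = "{_escape(name)}"',
            "        xmin = 0",
            f"        xmax = {dur:.6f}",
            f"        intervals: size = {len(filled)}",
        ]
        for i, (a, b, text) in enumerate(filled, start=1):
            out += [
                f"        intervals [{i}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{_escape(text)}"',
            ]
    Path(path).write_text("\n".join(out) + "\n")


def read_textgrid(path) -> SegmentTiers:
    """Parse a long-format TextGrid written by :func:`write_textgrid`.

    Non-empty interval texts matching a known class populate that tier;
    the tier name is used when the text is some other non-empty string.
    """
    lines = Path(path).read_text().splitlines()
    tiers = SegmentTiers()
    cur_tier = None
    xmin = xmax = None
    dur = 0.0
    for raw in lines:
        line = raw.strip()
        if line.startswith("name ="):
            cur_tier = line.split("=", 1)[1].strip().strip('"')
        elif line.startswith("xmin ="):
            xmin = float(line.split("=", 1)[1])
        elif line.startswith("xmax ="):
            xmax = float(line.split("=", 1)[1])
            dur = max(dur, xmax)
        elif line.startswith("text ="):
            text = line.split("=", 1)[1].strip().strip('"')
            if text and xmin is not None and xmax is not None and xmax > xmin:
                klass = text if text in CLASSES else cur_tier
                if klass in CLASSES:
                    tiers.tier(klass).append(
                        LabeledInterval(xmin, xmax, klass))
    tiers.duration_s = dur
    for name in CLASSES:
        tiers.tier(name).sort(key=lambda iv: iv.start_s)
    return tiers
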