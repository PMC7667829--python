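"""Writers for detector output: calls as BED, per-contig feature report as TSV."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import PatternCall
from .simulate import TruthLabel

__all__ = ["write_calls_bed", "calls_to_frame", "write_report_tsv", "write_truth_tsv"]


def write_calls_bed(calls: Sequence[PatternCall], path: str | Path) -> None:
    """Primary intervals of all non-standard calls as BED.

    The name column carries ``mode`` (and element kind), the score column
    the frequency ratio N (0 when not applicable); pac sites are emitted
    as 1 bp features.
    """
    with open(path, "w") as fh:
        for call in calls:
            if call.mode == "standard":
                continue
            for el in call.elements:
                n = el.frequency_ratio or 0
                fh.write(
                    f"{call.contig_id}\t{el.start}\t{el.end}\t{el.kind}\t{n:g}\t.\n"
                )
            for pos in call.pac_positions:
                fh.write(f"{call.contig_id}\t{pos}\t{pos + 1}\tpac_site\t0\t.\n")
            if not call.elements and not call.pac_positions:
                fh.write(f"{call.contig_id}\t0\t1\t{call.mode}\t0\t.\n")


_REPORT_COLUMNS = [
    "contig", "mode", "n_elements", "element_intervals", "frequency_ratio",
    "pac_positions", "headful_bp", "unevenness", "baseline", "wgs_cv",
    "qc_flags", "confident",
]


def calls_to_frame(calls: Sequence[PatternCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=_REPORT_COLUMNS).set_index("contig")
    rows = []
    for c in calls:
        rows.append({
            "contig": c.contig_id,
            "mode": c.mode,
            "n_elements": len(c.elements),
            "element_intervals": ";".join(f"{e.start}-{e.end}:{e.kind}" for e in c.elements),
            "frequency_ratio": c.frequency_ratio if c.frequency_ratio else np.nan,
            "pac_positions": ";".join(str(p) for p in c.pac_positions),
            "headful_bp": c.headful_estimate if c.headful_estimate else np.nan,
            "unevenness": round(c.unevenness, 3),
            "baseline": round(c.baseline, 4),
            "wgs_cv": round(c.wgs_cv, 4),
            "qc_flags": ";".join(sorted(c.qc_flags)),
            "confident": c.confident,
        })
    return pd.DataFrame(rows).set_index("contig")


def write_report_tsv(calls: Sequence[PatternCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t")


def write_truth_tsv(truths: Sequence[TruthLabel], path: str | Path) -> None:
    rows = []
    for t in truths:
        for el in (t.elements or [{}]):
            rows.append({
                "contig": t.contig_id,
                "mode": t.mode,
                "contamination": t.contamination,
                "element_mode": el.get("mode", ""),
                "start": el.get("start", ""),
                "end": el.get("end", ""),
                "frequency_ratio": el.get("frequency_ratio", ""),
                "headful": el.get("headful", ""),
                "pac_positions": ";".join(str(p) for p in el.get("pac_positions", [])),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
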