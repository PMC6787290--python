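"""QC summaries of long-read runs and pipeline report assembly."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["QcRow", "qc_summary", "format_ratio", "assemble_report"]


@dataclass(frozen=True)
class QcRow:
    sample: str
    ccs_count: int
    with_5p_primer: int
    with_3p_primer: int
    with_polya: int
    flnc_count: int
    mean_flnc_length: float
    flnc_to_ccs: float  # round-half-even to 2 decimals


def format_ratio(ratio: float) -> str:
    """Display form of the FLNC/CCS ratio: 2 decimals, trailing zeros
    trimmed (0.80 prints as "0.8")."""
    s = f"{ratio:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def qc_summary(metadata: Sequence[Mapping]) -> list[QcRow]:
    """Per-sample QC of circular-consensus reads.

    Each metadata row carries the per-sample counts: total CCS reads, reads
    with 5'/3' primers and poly-A, the full-length nonchimeric (FLNC)
    count, and the mean FLNC read length. The FLNC/CCS ratio is rounded
    half-even to two decimals.
    """
    rows = []
    for rec in metadata:
        ccs = int(rec["ccs_count"])
        flnc = int(rec["flnc_count"])
        if ccs == 0:
            raise ValueError(f"{rec.get('sample')}: CCS count 0, ratio undefined")
        if flnc > ccs:
            raise ValueError(
                f"{rec.get('sample')}: FLNC count {flnc} exceeds CCS {ccs}"
            )
        rows.append(
            QcRow(
                sample=str(rec["sample"]),
                ccs_count=ccs,
                with_5p_primer=int(rec.get("with_5p_primer", 0)),
                with_3p_primer=int(rec.get("with_3p_primer", 0)),
                with_polya=int(rec.get("with_polya", 0)),
                flnc_count=flnc,
                mean_flnc_length=float(rec.get("mean_flnc_length", 0.0)),
                flnc_to_ccs=round(flnc / ccs, 2),
            )
        )
    return sorted(rows, key=lambda r: r.sample)


def assemble_report(
    stage_outputs: Mapping[str, str],
    config_echo: Mapping | None = None,
    seed: int | None = None,
    version: str = "0",
    timestamp: str | None = None,
) -> str:
    """Assemble one human-readable report with a section per executed stage.

    Sections appear in sorted stage order, preceded by a header with the
    version, seed and configuration echo; output is deterministic (the
    timestamp line is emitted only when supplied).
    """
    if not stage_outputs:
        raise ValueError("at least one stage output required")
    lines = [f"# isotrx pipeline report (version {version})"]
    if timestamp is not None:
        lines.append(f"timestamp: {timestamp}")
    if seed is not None:
        lines.append(f"seed: {seed}")
    if config_echo:
        lines.append("config:")
        for key in sorted(config_echo):
            lines.append(f"  {key}: {config_echo[key]}")
    for stage in sorted(stage_outputs):
        lines.append("")
        lines.append(f"## {stage}")
        lines.append(stage_outputs[stage].rstrip("\n"))
    return "\n".join(lines) + "\n"
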