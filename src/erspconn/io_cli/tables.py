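"""Tab-separated result tables (UTF-8, header row)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_band_window_table",
    "write_er_cicoh_table",
    "write_cluster_report",
]


def write_band_window_table(path: str | Path, rows: list[dict]) -> Path:
    """ERSP summaries: subject, condition, channel, band, window, value_db."""
    df = pd.DataFrame(
        rows, columns=["subject", "condition", "channel", "band", "window", "value_db"]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_er_cicoh_table(path: str | Path, rows: list[dict]) -> Path:
    """ER-ciCOH maps: subject, condition, band, electrode, value."""
    df = pd.DataFrame(
        rows, columns=["subject", "condition", "band", "electrode", "value"]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_cluster_report(path: str | Path, rows: list[dict]) -> Path:
    """Cluster tests: measure, band, window, cluster id, sign, electrodes, mass, p."""
    df = pd.DataFrame(
        rows,
        columns=[
            "measure",
            "band",
            "window",
            "cluster_id",
            "sign",
            "electrodes",
            "mass",
            "p_corrected",
            "significant",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
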