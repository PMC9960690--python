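"""Convenience chains over the stage modules."""

from __future__ import annotations

import pandas as pd

from hrvstress.data_io import PipelineConfig, RRRecord
from hrvstress.features import extract_feature_table
from hrvstress.preprocess import preprocess_record


def dataset_feature_table(
    records: list[RRRecord],
    config: PipelineConfig | None = None,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Preprocess every record and extract the pooled 61-feature table.

    ``mode`` is ``"sliding"`` for lab-protocol records and ``"adjacent"``
    for ambulatory ones.
    """
    config = config or PipelineConfig()
    windows = []
    for record in records:
        w, _ = preprocess_record(record, config, mode)
        windows.extend(w)
    return extract_feature_table(windows, config)
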