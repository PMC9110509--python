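"""Run-log provenance: every pipeline stage appends what it did and with what."""

from __future__ import annotations

import datetime
import json
from pathlib import Path

RUN_LOG = "run_log.jsonl"


def append_provenance(out_dir, stage: str, **info) -> None:
    """Append a provenance block (stage, parameters, counts, seed) to the run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "stage": stage,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        **info,
    }
    with open(out_dir / RUN_LOG, "a") as fh:
        fh.write(json.dumps(block, default=str) + "\n")
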