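"""Reading and writing cohort artifacts as delimited text.

A cohort on disk is a directory with three files:

- ``values.csv`` — long format: patient_id, week, channel, t, value
  (the value field is empty for masked patient-weeks; the mask file is
  authoritative)
- ``mask.csv`` — patient_id, week, observed (0/1)
- ``meta.yaml`` — channel layout, week labels, seed and optional
  provenance columns
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layout import ChannelLayout, CohortTensor


def write_cohort(cohort: CohortTensor, out_dir: str | Path, seed: int | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lay = cohort.layout
    p = lay.points_per_cycle
    n, w, _ = cohort.values.shape

    pid = np.repeat(cohort.patient_ids, w * len(lay.channels) * p)
    week = np.tile(np.repeat(cohort.weeks, len(lay.channels) * p), n)
    chan = np.tile(np.repeat(lay.channels, p), n * w)
    t = np.tile(np.arange(p), n * w * len(lay.channels))
    vals = cohort.values.reshape(-1).astype(object)
    mask_rep = np.repeat(cohort.mask.reshape(-1), len(lay.channels) * p)
    vals[mask_rep == 0] = ""
    pd.DataFrame(
        {"patient_id": pid, "week": week, "channel": chan, "t": t, "value": vals}
    ).to_csv(out / "values.csv", index=False)

    pd.DataFrame(
        {
            "patient_id": np.repeat(cohort.patient_ids, w),
            "week": np.tile(cohort.weeks, n),
            "observed": cohort.mask.reshape(-1),
        }
    ).to_csv(out / "mask.csv", index=False)

    meta = {
        "layout": lay.to_dict(),
        "weeks": list(map(int, cohort.weeks)),
        "seed": seed,
        "patient_ids": list(cohort.patient_ids),
        "archetype_ids": cohort.archetype_ids,
        "provenance": cohort.provenance,
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out


def read_cohort(in_dir: str | Path) -> CohortTensor:
    src = Path(in_dir)
    meta = yaml.safe_load((src / "meta.yaml").read_text())
    lay = ChannelLayout.from_dict(meta["layout"])
    weeks = tuple(meta["weeks"])
    pids = [str(x) for x in meta["patient_ids"]]
    p = lay.points_per_cycle

    mask_df = pd.read_csv(src / "mask.csv")
    mask_df["patient_id"] = mask_df["patient_id"].astype(str)
    mask = np.zeros((len(pids), len(weeks)), dtype=int)
    widx = {wk: j for j, wk in enumerate(weeks)}
    pidx = {pid: i for i, pid in enumerate(pids)}
    for row in mask_df.itertuples(index=False):
        mask[pidx[str(row.patient_id)], widx[int(row.week)]] = int(row.observed)

    df = pd.read_csv(src / "values.csv")
    df["patient_id"] = df["patient_id"].astype(str)
    values = np.zeros((len(pids), len(weeks), lay.total_length))
    cidx = {ch: k for k, ch in enumerate(lay.channels)}
    col = (
        df["channel"].map(cidx).to_numpy() * p + df["t"].to_numpy()
    )
    rows_i = df["patient_id"].map(pidx).to_numpy()
    rows_j = df["week"].map(widx).to_numpy()
    v = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    values[rows_i, rows_j, col] = np.where(np.isnan(v), 0.0, v)

    return CohortTensor(
        values,
        mask,
        pids,
        weeks,
        lay,
        archetype_ids=meta.get("archetype_ids"),
        provenance=meta.get("provenance"),
    )


__all__ = ["write_cohort", "read_cohort"]
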