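"""On-body (wear) detection from near-body temperature.

The temperature stream is processed through the same cascade used for the
arm-angle metric (5-s rolling median, consecutive 5-s average, rolling 5-min
median) so that wear flags land on the same 5-s grid as the candidate
sleep-window metric.  A processed sample below 25 degrees Celsius marks the
device as off-body; exactly 25 degrees still counts as worn.
"""

from __future__ import annotations

import pandas as pd

WEAR_TEMP_C = 25.0
METRIC_EPOCH_S = 5


def preprocess_temperature(
    temp: pd.DataFrame | pd.Series,
    wear_threshold: float = WEAR_TEMP_C,
) -> pd.DataFrame:
    """Smooth a temperature stream and flag wear per 5-s epoch.

    Parameters
    ----------
    temp : Series or single-column DataFrame of temperatures (Celsius)
        indexed by timestamp.
    wear_threshold : processed temperatures strictly below this value are
        flagged non-wear.

    Returns
    -------
    DataFrame indexed by 5-s epoch start with columns ``temp_c`` (processed
    temperature) and ``worn`` (bool).
    """
    if isinstance(temp, pd.DataFrame):
        temp = temp.iloc[:, 0]
    if len(temp) == 0:
        raise ValueError("temperature stream is empty")
    med = temp.rolling(f"{METRIC_EPOCH_S}s", min_periods=1).median()
    avg = med.resample(f"{METRIC_EPOCH_S}s").mean()
    proc = avg.rolling(60, min_periods=1, center=True).median()  # 60 x 5 s = 5 min
    proc = proc.ffill().bfill()
    out = proc.rename("temp_c").to_frame()
    out["worn"] = out["temp_c"] >= wear_threshold
    out.index.name = "epoch_start"
    return out
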