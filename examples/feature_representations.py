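"""The three encodings of a binary sensor stream on a toy example.

A two-sensor stream is encoded as raw (the state as observed), change
point (1 exactly when a sensor flips state) and last sensor (1 on the most
recently flipped sensor until another one flips).  The printed columns
show how the same activity trace yields three different views: raw
captures duration, change point captures onsets/offsets, last sensor
captures "where the resident acted last".
"""

from datetime import datetime

import numpy as np

from hybridhmm import ObservationMatrix, change_point, concat, last_sensor, raw

stream = np.array([
    # door  pir
    [0, 0],
    [1, 0],   # door opens
    [1, 1],   # motion while the door is open
    [0, 1],
    [0, 0],
    [0, 0],
], dtype=np.uint8)
obs = ObservationMatrix(stream, ["door", "pir"], datetime(2012, 1, 2), 60)

full = concat([raw(obs), change_point(obs), last_sensor(obs)])
header = "  ".join(f"{c:>8s}" for c in full.column_names)
print(f"t  {header}")
for t, row in enumerate(full.values):
    cells = "  ".join(f"{v:>8d}" for v in row)
    print(f"{t}  {cells}")

print("\nraw: sensor active; cp: sensor just flipped; "
      "ls: flipped most recently")
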