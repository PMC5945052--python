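"""Confusion-table conventions on published count matrices.

The reproduced tables use 'PRECISION' for the row-wise diagonal ratio
(rows = actual) and 'RECALL' for the column-wise one — the reverse of the
conventional naming.  This script applies both accessors to the printed
count matrices and shows the Markdown rendering.
"""

import numpy as np

from steatoscope.metrics import (ConfusionMatrix, accuracy, col_recall,
                                 row_precision)

macro = ConfusionMatrix(np.array([
    [230, 8, 0, 25, 0],
    [6, 343, 0, 12, 0],
    [0, 1, 17, 27, 5],
    [15, 8, 14, 298, 2],
    [2, 4, 4, 7, 13]]),
    ["central_vein", "macro_fat", "bile_duct", "portal_vein",
     "portal_artery"])
micro = ConfusionMatrix(np.array([[7109, 1862], [2116, 7660]]),
                        ["micro_fat", "others"])

print("five-class macro table:")
print(macro.to_markdown())
print()
print(f"macro fat: precision {row_precision(macro, 'macro_fat')}%, "
      f"recall {col_recall(macro, 'macro_fat')}%")
print(f"binary micro table: precision {row_precision(micro, 'micro_fat')}%, "
      f"recall {col_recall(micro, 'micro_fat')}%, "
      f"accuracy {accuracy(micro)}%")
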