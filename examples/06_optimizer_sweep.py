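"""Small optimizer-comparison sweep via the CLI harness.

Runs a 2 (optimizer) x 2 (batch size) grid at tiny scale and prints the
tidy result table.  The same command works from a shell:

    gacnn compare --synthetic 20 --image-size 16 ... --out sweep.csv
"""

import tempfile
from pathlib import Path

import pandas as pd
from click.testing import CliRunner

from gacnn.cli import main

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "sweep.csv"
    res = CliRunner().invoke(main, [
        "compare", "--synthetic", "50", "--image-size", "16", "--n-patients", "8",
        "--conv-filters", "2", "--pool-every", "1", "--hidden-width", "0",
        "--optimizers", "gd,adam", "--batch-sizes", "16,32",
        "--iteration-counts", "300", "--seeds", "0,1", "--out", str(out),
    ])
    print(res.output)
    df = pd.read_csv(out)
    print(df[["optimizer", "batch_size", "iterations", "mean_accuracy", "sd_accuracy"]])
# mean/sd are over the replicate seeds; each cell is an independent
# train + patient-wise-test run.
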