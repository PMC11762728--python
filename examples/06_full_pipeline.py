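"""The whole chain on files, exactly as the command-line interface runs it:
simulate a dataset to disk, run the pipeline, print the report.
"""

import tempfile
from pathlib import Path

import divelev as dl
from divelev.pipeline import RunConfig, report, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    data_dir = Path(tmp) / "data"
    dl.generate_dataset(seed=7, n_tips=80, n_gradients=4).write(data_dir)

    cfg = RunConfig(
        tree_path=str(data_dir / "chronogram.nwk"),
        genus_table_path=str(data_dir / "genus_table.csv"),
        records_path=str(data_dir / "records.csv"),
        calibration_path=str(data_dir / "calibration.csv"),
        outdir=str(Path(tmp) / "out"),
    )
    result = run_pipeline(cfg)
    print(report(result))
    print("files written:", sorted(p.name for p in (Path(tmp) / "out").iterdir()))
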