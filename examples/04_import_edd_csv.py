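"""Load training data from a long-format (Experiment Data Depot style) CSV.

One row per (line, measurement); the declared response measurement is split
off from the input features, and replicate rows become separate instances
unless averaging is requested.
"""

import tempfile
from pathlib import Path

from dbtlearn import read_training_csv

csv_text = """Line Name,Measurement Type,Value
strain-1,HMGR,0.91
strain-1,ERG12,1.40
strain-1,limonene,22.0
strain-2,HMGR,1.55
strain-2,ERG12,0.62
strain-2,limonene,38.5
strain-2,HMGR,1.48
strain-2,ERG12,0.70
strain-2,limonene,36.1
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "study.csv"
    path.write_text(csv_text)

    data = read_training_csv(path, dialect="edd_long", response_names=["limonene"])
    print(f"{data.n_instances} instances x {data.n_features} features "
          f"(replicates split): {data.instance_ids}")
    print("inputs:\n", data.inputs)
    print("responses:", data.responses.ravel())

    merged = read_training_csv(path, dialect="edd_long",
                               response_names=["limonene"], merge_replicates=True)
    print(f"with --merge-replicates: {merged.n_instances} instances, "
          f"strain-2 limonene = {merged.responses[1, 0]:.2f} (replicate mean)")
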