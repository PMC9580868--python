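"""Run training remotely through the six-step job workflow.

1) create a job, 2) upload the features/labels JSON, 3) launch the
learning type, 4) poll the status until done, 5) list output files,
6) download the fitted model - then verify it matches local training.
"""

import tempfile
import threading
from pathlib import Path

import numpy as np

from voxelearn import (
    ClassifierSpec,
    compute_features_at,
    default_bank,
    load_model,
    simulate_strokes,
    standard_fixtures,
    train_classifier,
)
from voxelearn.annotation import training_table
from voxelearn.cloud_service import CloudClient, make_server, training_payload

bank = default_bank()
_, vol, gt = standard_fixtures()["blob_clean"]
ann = simulate_strokes(gt, seed=0)
ids = [t.voxel_id for t in ann.live_tags()]
X, y = training_table(ann, compute_features_at(vol, ids, bank))

server = make_server(port=0)
threading.Thread(target=server.serve_forever, daemon=True).start()
client = CloudClient("http://%s:%d" % server.server_address)

job = client.create_job()                                              # 1
client.upload_file(job, training_payload(X, y, feature_names=bank.names,
                                         schema_hash=bank.hash, seed=0),
                   "training.json")                                    # 2
client.launch_learning(job, "rfc")                                     # 3
status = client.wait(job)                                              # 4
files = client.list_files(job)                                         # 5
out = [f for f in files if f["role"] == "output"][0]
payload = client.get_file(job, out["file_id"])                         # 6
print(f"job {job}: {status}; downloaded {out['filename']} ({len(payload)} bytes)")

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "remote.vxl"
    path.write_bytes(payload)
    remote = load_model(path)
local = train_classifier(ClassifierSpec("RFC", seed=0), X, y,
                         feature_names=bank.names, schema_hash=bank.hash)
diff = np.max(np.abs(remote.predict_proba(X) - local.predict_proba(X)))
print(f"remote vs local max |dp| on the training voxels: {diff:.2e}")
server.shutdown(); server.server_close()
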