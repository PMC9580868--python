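"""Job-service lifecycle, the six-step HTTP workflow, remote/local
equivalence and job isolation."""

import io
import json
import threading

import numpy as np
import pytest

import voxelearn as vx
from voxelearn.cloud_service import (
    CloudClient,
    JobService,
    make_server,
    training_payload,
)
from voxelearn.errors import NotFoundError, StateError, ValidationError


@pytest.fixture()
def service():
    return JobService()


@pytest.fixture(scope="module")
def http_server():
    server = make_server(port=0)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield server
    server.shutdown()
    server.server_close()


@pytest.fixture(scope="module")
def client(http_server):
    host, port = http_server.server_address
    return CloudClient(f"http://{host}:{port}")


class TestJobLifecycle:
    def test_new_jobs_are_distinct_and_created(self, service):
        a, b = service.create_job(), service.create_job()
        assert a != b
        assert service.get_status(a) == "created"
        assert service.list_files(a) == []

    def test_upload_download_round_trip(self, service):
        job = service.create_job()
        fid = service.upload_file(job, b"\x00\x01payload", "in.bin")
        assert service.get_file(job, fid) == b"\x00\x01payload"
        (rec,) = service.list_files(job)
        assert rec["role"] == "input" and rec["size"] == 9

    def test_unknown_job_and_file_not_found(self, service):
        with pytest.raises(NotFoundError):
            service.get_status("deadbeef")
        job = service.create_job()
        other = service.create_job()
        fid = service.upload_file(job, b"x", "a.bin")
        with pytest.raises(NotFoundError):
            service.get_file(other, fid)  # file belongs to another job

    def test_launch_without_inputs_is_validation_error(self, service):
        job = service.create_job()
        with pytest.raises(ValidationError):
            service.launch_learning(job, "rfc")
        with pytest.raises(ValidationError):
            service.launch_learning(job, "quantum")

    def test_upload_after_launch_is_state_error(self, service, separable_clusters):
        X, y = separable_clusters
        job = service.create_job()
        service.upload_file(job, training_payload(X, y, seed=0), "training.json")
        service.launch_learning(job, "rfc")
        with pytest.raises(StateError):
            service.upload_file(job, b"late", "late.bin")
        assert service.wait(job) == "done"

    def test_corrupt_input_yields_error_status_with_message(self, service):
        job = service.create_job()
        service.upload_file(job, b"{broken json", "training.json")
        service.launch_learning(job, "rfc")
        assert service.wait(job) == "error"
        assert service.get_error(job)

    def test_training_job_completes_with_model_output(self, service, separable_clusters):
        X, y = separable_clusters
        job = service.create_job()
        service.upload_file(job, training_payload(X, y, seed=0), "training.json")
        service.launch_learning(job, "rfc")
        assert service.wait(job) == "done"
        outputs = [f for f in service.list_files(job) if f["role"] == "output"]
        assert outputs and outputs[0]["filename"] == "model.vxl"


class TestConcurrentIsolation:
    def test_four_simultaneous_jobs_produce_their_own_outputs(self, service):
        rng = np.random.default_rng(0)
        jobs = {}
        for shift in range(4):
            X = np.vstack([
                rng.normal(-2 - shift, 0.4, size=(20, 3)),
                rng.normal(2 + shift, 0.4, size=(20, 3)),
            ])
            y = np.array([0] * 20 + [1] * 20)
            job = service.create_job()
            service.upload_file(job, training_payload(X, y, seed=shift), "training.json")
            jobs[job] = (X, y, shift)
        for job in jobs:
            service.launch_learning(job, "rfc")
        for job, (X, y, shift) in jobs.items():
            assert service.wait(job) == "done"
            payload = [
                service.get_file(job, f["file_id"])
                for f in service.list_files(job)
                if f["role"] == "output"
            ][0]
            import tempfile
            from pathlib import Path

            with tempfile.TemporaryDirectory() as td:
                p = Path(td) / "m.vxl"
                p.write_bytes(payload)
                model = vx.load_model(p)
            assert model.metadata["seed"] == shift
            acc = ((model.predict_proba(X) >= 0.5).astype(int) == y).mean()
            assert acc == 1.0


class TestHttpWorkflow:
    def test_six_step_workflow_on_blob_clean(self, client, fixtures, bank, tmp_path):
        """Create job, upload, launch, poll, list, download — then the
        downloaded model must reproduce local training exactly."""
        from voxelearn.annotation import training_table
        from voxelearn.synthetic_data import simulate_strokes

        _, vol, gt = fixtures["blob_clean"]
        ann = simulate_strokes(gt, seed=0)
        ids = [t.voxel_id for t in ann.live_tags()]
        fm = vx.compute_features_at(vol, ids, bank)
        X, y = training_table(ann, fm)

        job = client.create_job()                                    # 1
        client.upload_file(                                          # 2
            job,
            training_payload(X, y, feature_names=bank.names,
                             schema_hash=bank.hash, seed=0),
            "training.json",
        )
        client.launch_learning(job, "rfc")                           # 3
        assert client.wait(job) == "done"                            # 4
        files = client.list_files(job)                               # 5
        outputs = [f for f in files if f["role"] == "output"]
        assert outputs
        payload = client.get_file(job, outputs[0]["file_id"])        # 6

        path = tmp_path / "remote.vxl"
        path.write_bytes(payload)
        remote = vx.load_model(path)
        local = vx.train_classifier(
            vx.ClassifierSpec("RFC", seed=0), X, y,
            feature_names=bank.names, schema_hash=bank.hash,
        )
        pm_remote = vx.infer_volume(remote, vol, bank)
        pm_local = vx.infer_volume(local, vol, bank)
        assert np.max(np.abs(pm_remote.data - pm_local.data)) <= 1e-6

    def test_http_errors_map_to_exceptions(self, client):
        with pytest.raises(NotFoundError):
            client.get_status("feedfacecafe")
        job = client.create_job()
        with pytest.raises(ValidationError):
            client.launch_learning(job, "rfc")  # no inputs yet

    def test_remote_inference_job(self, client, fixtures, bank, blob_noisy_rfc, tmp_path):
        import tifffile

        _, vol, gt = fixtures["blob_noisy"]
        sub = vx.VolumeStack(data=vol.data[:16, :16, :16])
        mpath = tmp_path / "m.vxl"
        vx.save_model(blob_noisy_rfc, mpath)
        buf = io.BytesIO()
        tifffile.imwrite(buf, sub.data.astype(np.float32), photometric="minisblack")

        job = client.create_job()
        client.upload_file(job, mpath.read_bytes(), "model.vxl")
        client.upload_file(job, buf.getvalue(), "volume.tif")
        client.launch_learning(job, "inference")
        assert client.wait(job) == "done"
        outputs = [f for f in client.list_files(job) if f["role"] == "output"]
        prob_bytes = client.get_file(job, outputs[0]["file_id"])
        remote_pm = tifffile.imread(io.BytesIO(prob_bytes))
        local_pm = vx.infer_volume(blob_noisy_rfc, sub, bank)
        assert np.max(np.abs(remote_pm - local_pm.data)) <= 1e-6
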