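"""Asynchronous learning-job service.

A thin client drives training/inference remotely through six REST calls:
create a job, upload its input files, launch a learning type, poll the
status until it leaves ``running``, list the output files, download them.
Job state follows ``created -> running -> done | error`` (the initial
``created`` state makes uploads-before-launch well defined).

The service itself is an in-process :class:`JobService` — jobs execute on
worker threads and are fully isolated from one another — and the HTTP
layer is a small stdlib ``http.server`` application exposing the endpoints
verbatim:

    POST /jobs                      -> {"job_id": ...}
    POST /jobs/{jobid}/file        -> {"file_id": ...}   (?filename=...)
    PUT  /learning/{jobid}          body {"type": "rfc" | ... | "inference"}
    GET  /jobs/{jobid}/status      -> {"status": "created|running|done|error"}
    GET  /jobs/{jobid}/files       -> {"files": [...]}
    GET  /jobs/{jobid}/files/{fileid} -> raw bytes

Payload conventions: training jobs take one ``*.json`` input holding
``{"model": ..., "feature_names": [...], "X": [[...]], "y": [...],
"seed": ...}``; inference jobs take a ``*.vxl`` model archive plus a
``*.tif`` volume and emit ``probabilities.tif``.
"""

from __future__ import annotations

import io
import json
import re
import tempfile
import threading
import time
import uuid
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from urllib.parse import parse_qs, urlparse

import numpy as np

from .errors import NotFoundError, StateError, ValidationError
from .learners import (
    ClassifierSpec,
    predict_proba,
    load_model,
    save_model,
    train_classifier,
    train_strong,
)

TRAINING_TYPES = ("rfc", "mlp", "xgb", "svm", "nbc", "strong")
STATUSES = ("created", "running", "done", "error")


@dataclass
class FileRecord:
    file_id: str
    job_id: str
    role: str  # "input" | "output"
    filename: str
    size: int
    payload: bytes = field(repr=False, default=b"")

    def describe(self) -> dict:
        return {
            "file_id": self.file_id,
            "filename": self.filename,
            "role": self.role,
            "size": self.size,
        }


@dataclass
class Job:
    job_id: str
    status: str = "created"
    learning_type: str | None = None
    created_at: float = field(default_factory=time.time)
    finished_at: float | None = None
    error_message: str = ""
    files: dict[str, FileRecord] = field(default_factory=dict)


class JobService:
    """In-memory job store with one worker thread per launched job."""

    def __init__(self):
        self._jobs: dict[str, Job] = {}
        self._lock = threading.RLock()
        self._threads: list[threading.Thread] = []

    # -- lifecycle ---------------------------------------------------------
    def create_job(self) -> str:
        job_id = uuid.uuid4().hex[:12]
        with self._lock:
            self._jobs[job_id] = Job(job_id=job_id)
        return job_id

    def _get(self, job_id: str) -> Job:
        job = self._jobs.get(job_id)
        if job is None:
            raise NotFoundError(f"unknown job {job_id!r}")
        return job

    def upload_file(self, job_id: str, payload: bytes, filename: str) -> str:
        with self._lock:
            job = self._get(job_id)
            if job.status != "created":
                raise StateError(f"cannot upload to a job in status {job.status!r}")
            file_id = uuid.uuid4().hex[:12]
            job.files[file_id] = FileRecord(
                file_id=file_id,
                job_id=job_id,
                role="input",
                filename=filename,
                size=len(payload),
                payload=bytes(payload),
            )
        return file_id

    def launch_learning(self, job_id: str, learning_type: str) -> dict:
        with self._lock:
            job = self._get(job_id)
            if job.status != "created":
                raise StateError(f"job {job_id} already launched (status {job.status!r})")
            self._validate_inputs(job, learning_type)
            job.status = "running"
            job.learning_type = learning_type
            thread = threading.Thread(
                target=self._execute, args=(job_id,), daemon=True
            )
            self._threads.append(thread)
        thread.start()
        return {"job_id": job_id, "status": "running"}

    def get_status(self, job_id: str) -> str:
        with self._lock:
            return self._get(job_id).status

    def get_error(self, job_id: str) -> str:
        with self._lock:
            return self._get(job_id).error_message

    def list_files(self, job_id: str) -> list[dict]:
        with self._lock:
            return [f.describe() for f in self._get(job_id).files.values()]

    def get_file(self, job_id: str, file_id: str) -> bytes:
        with self._lock:
            job = self._get(job_id)
            rec = job.files.get(file_id)
            if rec is None:
                raise NotFoundError(f"unknown file {file_id!r} in job {job_id}")
            return rec.payload

    def wait(self, job_id: str, timeout: float = 120.0, poll: float = 0.05) -> str:
        """Poll the status until the job leaves ``running`` (Fig-style loop)."""
        deadline = time.time() + timeout
        while time.time() < deadline:
            status = self.get_status(job_id)
            if status in ("done", "error"):
                return status
            time.sleep(poll)
        raise TimeoutError(f"job {job_id} still {self.get_status(job_id)!r}")

    # -- execution ---------------------------------------------------------
    @staticmethod
    def _inputs_by_suffix(job: Job, suffix: str) -> list[FileRecord]:
        return [
            f
            for f in job.files.values()
            if f.role == "input" and f.filename.lower().endswith(suffix)
        ]

    def _validate_inputs(self, job: Job, learning_type: str) -> None:
        if learning_type in TRAINING_TYPES:
            if not self._inputs_by_suffix(job, ".json"):
                raise ValidationError(
                    f"training job needs a features/labels JSON input"
                )
        elif learning_type == "inference":
            if not self._inputs_by_suffix(job, ".vxl"):
                raise ValidationError("inference job needs a .vxl model input")
            if not self._inputs_by_suffix(job, ".tif"):
                raise ValidationError("inference job needs a .tif volume input")
        else:
            raise ValidationError(
                f"unknown learning type {learning_type!r}; "
                f"expected one of {TRAINING_TYPES + ('inference',)}"
            )

    def _register_output(self, job: Job, filename: str, payload: bytes) -> None:
        file_id = uuid.uuid4().hex[:12]
        job.files[file_id] = FileRecord(
            file_id=file_id,
            job_id=job.job_id,
            role="output",
            filename=filename,
            size=len(payload),
            payload=payload,
        )

    def _execute(self, job_id: str) -> None:
        job = self._jobs[job_id]
        try:
            if job.learning_type in TRAINING_TYPES:
                outputs = _run_training(job)
            else:
                outputs = _run_inference(job)
            with self._lock:
                for name, payload in outputs.items():
                    self._register_output(job, name, payload)
                job.status = "done"
                job.finished_at = time.time()
        except Exception as exc:  # noqa: BLE001 - surfaced via the job record
            with self._lock:
                job.status = "error"
                job.error_message = f"{type(exc).__name__}: {exc}"
                job.finished_at = time.time()


def _run_training(job: Job) -> dict[str, bytes]:
    doc_rec = JobService._inputs_by_suffix(job, ".json")[0]
    doc = json.loads(doc_rec.payload.decode())
    X = np.asarray(doc["X"], dtype=np.float64)
    y = np.asarray(doc["y"], dtype=np.int64)
    seed = int(doc.get("seed", 0))
    names = doc.get("feature_names")
    schema_hash = doc.get("schema_hash")
    kind = job.learning_type
    if kind == "strong":
        model = train_strong(
            X, y, seed=seed, feature_names=names, schema_hash=schema_hash
        )
    else:
        model = train_classifier(
            ClassifierSpec(kind.upper(), doc.get("hyperparameters", {}), seed=seed),
            X,
            y,
            feature_names=names,
            schema_hash=schema_hash,
        )
    with tempfile.TemporaryDirectory() as td:
        out = Path(td) / "model.vxl"
        save_model(model, out)
        payload = out.read_bytes()
    return {"model.vxl": payload}


def _run_inference(job: Job) -> dict[str, bytes]:
    import tifffile

    from .feature_bank import default_bank
    from .inference import infer_volume
    from .volume_io import VolumeStack, write_volume

    model_rec = JobService._inputs_by_suffix(job, ".vxl")[0]
    vol_rec = JobService._inputs_by_suffix(job, ".tif")[0]
    with tempfile.TemporaryDirectory() as td:
        mpath = Path(td) / "model.vxl"
        mpath.write_bytes(model_rec.payload)
        model = load_model(mpath)
        data = tifffile.imread(io.BytesIO(vol_rec.payload))
        vol = VolumeStack(data=data, name=vol_rec.filename)
        pm = infer_volume(model, vol, default_bank())
        opath = Path(td) / "probabilities.tif"
        write_volume(pm, opath, format="tiff")
        payload = opath.read_bytes()
    return {"probabilities.tif": payload}


# ---------------------------------------------------------------------------
# HTTP layer (stdlib)

_ROUTES = {
    "jobs": re.compile(r"^/jobs/?$"),
    "file": re.compile(r"^/jobs/(?P<job>[0-9a-f]+)/file/?$"),
    "status": re.compile(r"^/jobs/(?P<job>[0-9a-f]+)/status/?$"),
    "files": re.compile(r"^/jobs/(?P<job>[0-9a-f]+)/files/?$"),
    "one_file": re.compile(r"^/jobs/(?P<job>[0-9a-f]+)/files/(?P<file>[0-9a-f]+)/?$"),
    "learning": re.compile(r"^/learning/(?P<job>[0-9a-f]+)/?$"),
}


def make_handler(service: JobService):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet server
            pass

        def _send_json(self, obj, code=200):
            body = json.dumps(obj).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _send_bytes(self, payload: bytes):
            self.send_response(200)
            self.send_header("Content-Type", "application/octet-stream")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def _error(self, exc: Exception):
            code = 500
            if isinstance(exc, NotFoundError):
                code = 404
            elif isinstance(exc, StateError):
                code = 409
            elif isinstance(exc, (ValidationError, json.JSONDecodeError, KeyError)):
                code = 400
            self._send_json({"error": str(exc)}, code=code)

        def _body(self) -> bytes:
            length = int(self.headers.get("Content-Length", 0))
            return self.rfile.read(length) if length else b""

        def do_POST(self):
            parsed = urlparse(self.path)
            try:
                if _ROUTES["jobs"].match(parsed.path):
                    self._send_json({"job_id": service.create_job()}, code=201)
                    return
                m = _ROUTES["file"].match(parsed.path)
                if m:
                    qs = parse_qs(parsed.query)
                    filename = (
                        qs.get("filename", [None])[0]
                        or self.headers.get("X-Filename")
                        or "upload.bin"
                    )
                    fid = service.upload_file(m["job"], self._body(), filename)
                    self._send_json({"file_id": fid}, code=201)
                    return
                self._send_json({"error": "no such endpoint"}, code=404)
            except Exception as exc:  # noqa: BLE001
                self._error(exc)

        def do_PUT(self):
            parsed = urlparse(self.path)
            try:
                m = _ROUTES["learning"].match(parsed.path)
                if m:
                    doc = json.loads(self._body() or b"{}")
                    ack = service.launch_learning(m["job"], doc["type"])
                    self._send_json(ack, code=202)
                    return
                self._send_json({"error": "no such endpoint"}, code=404)
            except Exception as exc:  # noqa: BLE001
                self._error(exc)

        def do_GET(self):
            parsed = urlparse(self.path)
            try:
                m = _ROUTES["status"].match(parsed.path)
                if m:
                    status = service.get_status(m["job"])
                    doc = {"status": status}
                    if status == "error":
                        doc["message"] = service.get_error(m["job"])
                    self._send_json(doc)
                    return
                m = _ROUTES["one_file"].match(parsed.path)
                if m:
                    self._send_bytes(service.get_file(m["job"], m["file"]))
                    return
                m = _ROUTES["files"].match(parsed.path)
                if m:
                    self._send_json({"files": service.list_files(m["job"])})
                    return
                self._send_json({"error": "no such endpoint"}, code=404)
            except Exception as exc:  # noqa: BLE001
                self._error(exc)

    return Handler


def make_server(port: int = 0, service: JobService | None = None) -> ThreadingHTTPServer:
    """Build (but do not start) an HTTP server wrapping a JobService."""
    service = service or JobService()
    server = ThreadingHTTPServer(("127.0.0.1", port), make_handler(service))
    server.service = service  # type: ignore[attr-defined]
    return server


class CloudClient:
    """Minimal HTTP client scripting the six-step workflow."""

    def __init__(self, base_url: str):
        self.base_url = base_url.rstrip("/")

    def _request(self, method: str, path: str, body: bytes | None = None,
                 headers: dict | None = None):
        import urllib.error
        import urllib.request

        req = urllib.request.Request(
            self.base_url + path, data=body, method=method, headers=headers or {}
        )
        try:
            with urllib.request.urlopen(req) as resp:
                return resp.read(), resp.status
        except urllib.error.HTTPError as exc:
            detail = exc.read().decode(errors="replace")
            if exc.code == 404:
                raise NotFoundError(detail) from exc
            if exc.code == 409:
                raise StateError(detail) from exc
            raise ValidationError(detail) from exc

    def create_job(self) -> str:
        body, _ = self._request("POST", "/jobs")
        return json.loads(body)["job_id"]

    def upload_file(self, job_id: str, payload: bytes, filename: str) -> str:
        body, _ = self._request(
            "POST", f"/jobs/{job_id}/file?filename={filename}", body=payload
        )
        return json.loads(body)["file_id"]

    def launch_learning(self, job_id: str, learning_type: str) -> dict:
        body, _ = self._request(
            "PUT", f"/learning/{job_id}",
            body=json.dumps({"type": learning_type}).encode(),
            headers={"Content-Type": "application/json"},
        )
        return json.loads(body)

    def get_status(self, job_id: str) -> str:
        body, _ = self._request("GET", f"/jobs/{job_id}/status")
        return json.loads(body)["status"]

    def list_files(self, job_id: str) -> list[dict]:
        body, _ = self._request("GET", f"/jobs/{job_id}/files")
        return json.loads(body)["files"]

    def get_file(self, job_id: str, file_id: str) -> bytes:
        body, _ = self._request("GET", f"/jobs/{job_id}/files/{file_id}")
        return body

    def wait(self, job_id: str, timeout: float = 120.0, poll: float = 0.05) -> str:
        deadline = time.time() + timeout
        while time.time() < deadline:
            status = self.get_status(job_id)
            if status in ("done", "error"):
                return status
            time.sleep(poll)
        raise TimeoutError(f"job {job_id} still running")


def training_payload(X, y, feature_names=None, schema_hash=None, seed: int = 0) -> bytes:
    """Serialise a training table into the service's JSON input dialect."""
    doc = {
        "X": np.asarray(X, dtype=float).tolist(),
        "y": np.asarray(y, dtype=int).tolist(),
        "seed": int(seed),
    }
    if feature_names is not None:
        doc["feature_names"] = list(feature_names)
    if schema_hash is not None:
        doc["schema_hash"] = schema_hash
    return json.dumps(doc).encode()


def serve(port: int = 8000) -> None:
    """Run the learning service until interrupted."""
    server = make_server(port=port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
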