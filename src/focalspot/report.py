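"""JSON measurement reports: write, read, and minimally validate.

A report is the durable QA record of one measurement: the offset, every
intermediate the auditor needs to recompute it (field centres, separations,
factors, geometry), and software provenance. The schema is documented in
``docs/report_schema.json``.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone

REPORT_VERSION = 1

_REQUIRED = {
    "epid": (
        "offset_mm",
        "field_centers_mm",
        "jaw_centroid_mm",
        "mlc_centroid_mm",
        "separation_mm",
        "factors",
        "geometry_mm",
        "params",
    ),
    "ic": ("offset_mm", "sensitivities", "geometry_mm"),
}


def write_report(result, path) -> dict:
    """Serialise a results object (anything with ``to_dict``) to JSON."""
    from . import __version__

    body = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    body.setdefault("kind", "epid")
    body["software"] = {"name": "focalspot", "version": __version__}
    body["report_version"] = REPORT_VERSION
    body["generated"] = datetime.now(timezone.utc).isoformat()
    validate_report(body)
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2)
    return body


def read_report(path) -> dict:
    with open(path) as fh:
        body = json.load(fh)
    validate_report(body)
    return body


def validate_report(body: dict) -> None:
    """Check required keys and basic types; raise ``ValueError`` otherwise."""
    kind = body.get("kind")
    if kind not in _REQUIRED:
        raise ValueError(f"unknown report kind {kind!r}")
    missing = [k for k in _REQUIRED[kind] if k not in body]
    if missing:
        raise ValueError(f"report is missing keys: {missing}")
    offset = body["offset_mm"]
    if not isinstance(offset, dict) or not {"crossplane", "inplane"} <= set(offset):
        raise ValueError("offset_mm must map crossplane and inplane")
    for key, value in offset.items():
        if value is not None and not isinstance(value, (int, float)):
            raise ValueError(f"offset_mm[{key}] must be numeric or null")
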