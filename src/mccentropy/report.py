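"""Machine-readable reports of an entropy decomposition.

JSON keeps full precision and round-trips exactly; TSV is the
human-readable table with one row per term in the fixed decomposition
order, values printed to 1 decimal place.  Timestamps are deliberately
absent so identical runs produce byte-identical reports.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

from .errors import MCCError
from .pipeline import EntropyDecomposition, TERM_ORDER


def write_report(decomposition: EntropyDecomposition, path, fmt: str = "json") -> None:
    """Write a report; ``fmt`` is 'json' or 'tsv'."""
    try:
        if fmt == "json":
            payload = asdict(decomposition)
            payload["S_total"] = decomposition.S_total
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
                fh.write("\n")
        elif fmt == "tsv":
            with open(path, "w") as fh:
                fh.write("term\tentropy_J_per_K_mol\n")
                for name in TERM_ORDER:
                    fh.write(f"{name}\t{getattr(decomposition, name):.1f}\n")
                fh.write(f"S_total\t{decomposition.S_total:.1f}\n")
                excl = sum(decomposition.zero_mode_exclusions.values())
                fh.write(f"# zero-frequency modes excluded: {excl}\n")
        else:
            raise MCCError(f"unknown report format {fmt!r}")
    except OSError as exc:
        raise MCCError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> EntropyDecomposition:
    """Read a JSON report back into an :class:`EntropyDecomposition`."""
    if not os.path.exists(path):
        raise MCCError(f"report not found: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("S_total", None)
    return EntropyDecomposition(**payload)
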