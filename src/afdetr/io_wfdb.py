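"""Optional adapter for PhysioNet WFDB records (guarded import).

Reading ``.dat/.hea`` signals and ``.atr/.qrs`` annotations requires the
``wfdb`` package, which is an optional dependency (``pip install
afdetr[wfdb]``).  The adapter converts a WFDB record plus its annotation
file into the package's :class:`~afdetr.records.EcgRecord`; rhythm change
annotations (aux notes starting with ``(``) become half-open rhythm
intervals.
"""

from __future__ import annotations

import numpy as np

from .records import EcgRecord

__all__ = ["read_wfdb_record"]


def _require_wfdb():
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install it with: pip install wfdb"
        ) from exc
    return wfdb


def read_wfdb_record(record_path: str, annotation_ext: str = "atr",
                     channel: int | str = 0) -> EcgRecord:
    """Read one WFDB record + annotations into an :class:`EcgRecord`.

    ``channel`` selects the lead by index or by signal name.  Beat
    annotations keep their symbol; rhythm aux notes ``(X`` open an interval
    that closes at the next rhythm change (or the record end).
    """
    wfdb = _require_wfdb()
    rec = wfdb.rdrecord(record_path)
    if isinstance(channel, str):
        names = list(rec.sig_name)
        if channel not in names:
            raise ValueError(f"lead {channel!r} not in {names}")
        ch = names.index(channel)
        lead_name = channel
    else:
        ch = int(channel)
        lead_name = rec.sig_name[ch]
    samples = np.asarray(rec.p_signal[:, ch], dtype=np.float64)

    ann = wfdb.rdann(record_path, annotation_ext)
    beat_symbols = set("NLRBAaJSVrFejnE/fQ?")
    beats = [
        (int(s), sym)
        for s, sym in zip(ann.sample, ann.symbol)
        if sym in beat_symbols
    ]
    changes = [
        (int(s), aux.rstrip("\x00"))
        for s, sym, aux in zip(ann.sample, ann.symbol, ann.aux_note)
        if aux and aux.startswith("(")
    ]
    rhythms = []
    for i, (start, label) in enumerate(changes):
        end = changes[i + 1][0] if i + 1 < len(changes) else len(samples)
        if end > start:
            rhythms.append((start, min(end, len(samples)), label))
    return EcgRecord(samples=samples, fs=float(rec.fs), lead_name=lead_name,
                     beats=beats, rhythms=rhythms,
                     record_id=record_path.rsplit("/", 1)[-1])
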