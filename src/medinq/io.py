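"""Reading and writing the pipeline's file formats.

Inquiries come in as CSV or JSONL with ``id``, ``text`` and optional
``language`` (default ``en``) fields; any other fields are kept as
metadata. Sentences and weak labels travel as JSONL, one object per line.
Non-English inquiries are not translated: they are tagged ``untranslated``
in their metadata and passed through unchanged.
"""

from __future__ import annotations

import json

import pandas as pd

from .preprocessing import CleanSentence, RawInquiry
from .rule_engine import SentenceLabel

__all__ = [
    "read_inquiries",
    "write_sentences",
    "read_sentences",
    "write_labels",
    "read_labels",
    "mark_untranslated",
]


def read_inquiries(path) -> list[RawInquiry]:
    """Load inquiries from CSV or JSONL (by file extension)."""
    path = str(path)
    records: list[dict] = []
    if path.endswith(".jsonl") or path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    records.append(json.loads(line))
    else:
        records = pd.read_csv(path, dtype=str).fillna("").to_dict("records")
    out: list[RawInquiry] = []
    seen: set[str] = set()
    for rec in records:
        iid = str(rec.get("id", ""))
        text = str(rec.get("text", ""))
        if not iid or iid in seen:
            raise ValueError(f"missing or duplicate inquiry id {iid!r}")
        seen.add(iid)
        meta = {k: v for k, v in rec.items()
                if k not in ("id", "text", "language")}
        out.append(RawInquiry(iid, text, str(rec.get("language") or "en"),
                              meta or None))
    return out


def mark_untranslated(inquiries: list[RawInquiry]) -> list[RawInquiry]:
    """Tag non-English inquiries; translation itself is out of scope."""
    out = []
    for inq in inquiries:
        if inq.language != "en":
            meta = dict(inq.metadata or {})
            meta["untranslated"] = True
            inq = RawInquiry(inq.id, inq.text, inq.language, meta)
        out.append(inq)
    return out


def write_sentences(sentences: list[CleanSentence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps({
                "inquiry_id": s.inquiry_id, "index": s.index,
                "text": s.text, "tokens": list(s.tokens),
            }) + "\n")


def read_sentences(path) -> list[CleanSentence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(CleanSentence(d["inquiry_id"], int(d["index"]),
                                     d["text"], tuple(d["tokens"])))
    return out


def write_labels(labels: list[SentenceLabel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab in labels:
            fh.write(json.dumps({
                "inquiry_id": lab.inquiry_id, "index": lab.index,
                "text": lab.text, "subcategory": lab.subcategory,
                "root": lab.root, "rule_id": lab.rule_id,
            }) + "\n")


def read_labels(path) -> list[SentenceLabel]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(SentenceLabel(d["inquiry_id"], int(d["index"]),
                                     d["text"], d["subcategory"], d["root"],
                                     d.get("rule_id")))
    return out
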