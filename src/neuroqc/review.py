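"""Multi-rater visual review of pre-generated snapshots.

A *gallery* is an ordered list of snapshot entries joined to the per-test
outcomes collected from validation reports; raters walk through it,
assigning each snapshot a quality score and a free-text comment.  Every
action is appended to a TSV log — history is never rewritten — and the
"current" view (latest record per snapshot and rater) is derived from it.
Checkpoint-aware navigation jumps from one failed case to the next.

The storage, navigation and export operations are plain functions,
testable without a browser; :func:`serve` wraps them in a minimal
single-page web application on the standard-library HTTP server.
"""

from __future__ import annotations

import datetime
import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["Gallery", "GalleryEntry", "ReviewStore", "load_gallery",
           "next_failed", "export_reviews", "serve"]

SCORE_LABELS = {0: "fail", 1: "doubtful", 2: "pass"}


@dataclass
class GalleryEntry:
    snapshot_id: str
    image_path: Path
    session_id: str = ""
    subject_id: str = ""
    outcomes: dict = field(default_factory=dict)  # test_id -> bool

    @property
    def session_link(self) -> str:
        return f"session://{self.subject_id}/{self.session_id}"


@dataclass
class Gallery:
    entries: list

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, index):
        return self.entries[index]

    @property
    def test_ids(self) -> list:
        ids: list = []
        for entry in self.entries:
            for t in entry.outcomes:
                if t not in ids:
                    ids.append(t)
        return ids


def load_gallery(snapshot_dir, manifest=None) -> Gallery:
    """Build a gallery from a folder of snapshots and a collect manifest.

    ``manifest`` is a DataFrame or CSV path as written by
    :func:`neuroqc.collect.collect_snapshots`; snapshots absent from the
    manifest carry empty outcomes.  Order is lexicographic by snapshot id,
    hence deterministic.
    """
    snapshot_dir = Path(snapshot_dir)
    if manifest is not None and not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    by_id = {}
    if manifest is not None and not manifest.empty:
        meta_cols = {"snapshot_id", "session_id", "subject_id"}
        for _, row in manifest.iterrows():
            outcomes = {k: bool(v) for k, v in row.items()
                        if k not in meta_cols and pd.notna(v)}
            by_id[row["snapshot_id"]] = (row.get("session_id", ""),
                                         row.get("subject_id", ""), outcomes)
    entries = []
    for path in sorted(snapshot_dir.iterdir()):
        if path.suffix.lower() not in (".png", ".gif", ".jpg", ".jpeg"):
            continue
        session_id, subject_id, outcomes = by_id.get(path.name, ("", "", {}))
        entries.append(GalleryEntry(path.name, path, session_id, subject_id,
                                    outcomes))
    return Gallery(entries)


class ReviewStore:
    """Append-only TSV log of review records with a derived current view.

    Columns: snapshot_id, rater, score, comment, timestamp.  Appends take
    an exclusive file lock so concurrent raters interleave safely; nothing
    ever removes or mutates stored rows.
    """

    COLUMNS = ["snapshot_id", "rater", "score", "comment", "timestamp"]

    def __init__(self, path, scale=(0, 2)):
        self.path = Path(path)
        self.scale = scale
        if not self.path.exists():
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("\t".join(self.COLUMNS) + "\n")

    def append(self, snapshot_id: str, rater: str, score: int,
               comment: str = "", timestamp: Optional[str] = None) -> dict:
        score = int(score)
        if not self.scale[0] <= score <= self.scale[1]:
            raise ValueError(
                f"score {score} outside scale [{self.scale[0]}, {self.scale[1]}]")
        if not rater:
            raise ValueError("rater name required")
        record = {
            "snapshot_id": snapshot_id,
            "rater": rater,
            "score": score,
            "comment": (comment or "").replace("\t", " ").replace("\n", " "),
            "timestamp": timestamp or datetime.datetime.now(
                datetime.timezone.utc).isoformat(timespec="seconds"),
        }
        line = "\t".join(str(record[c]) for c in self.COLUMNS) + "\n"
        with open(self.path, "a") as fh:
            try:
                import fcntl
                fcntl.flock(fh, fcntl.LOCK_EX)
            except (ImportError, OSError):
                pass
            fh.write(line)
        return record

    def history(self) -> pd.DataFrame:
        return pd.read_csv(self.path, sep="\t", keep_default_na=False,
                           dtype={"snapshot_id": str, "rater": str,
                                  "comment": str})

    def current(self) -> pd.DataFrame:
        """Latest record per (snapshot, rater): a pure function of history."""
        history = self.history()
        if history.empty:
            return history
        return (history.groupby(["snapshot_id", "rater"], as_index=False)
                .last())


def next_failed(gallery: Gallery, test_id: str, current_index: int):
    """Smallest index after ``current_index`` whose outcome for ``test_id``
    is a failure, wrapping around to the first failed case.

    Returns ``(index, notice)``; with no failed case the index is
    unchanged and the notice says so.
    """
    n = len(gallery)
    failed = [i for i in range(n)
              if gallery[i].outcomes.get(test_id) is False]
    if not failed:
        return current_index, f"no failed case for {test_id}"
    for offset in range(1, n + 1):
        index = (current_index + offset) % n
        if index in failed:
            return index, None
    return current_index, f"no failed case for {test_id}"  # unreachable


def export_reviews(store: ReviewStore, out_path=None) -> pd.DataFrame:
    """Current view as a spreadsheet: one row per (snapshot, rater)."""
    table = store.current()
    if table.empty:
        table = pd.DataFrame(columns=ReviewStore.COLUMNS)
    table = table[ReviewStore.COLUMNS]
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table


# --------------------------------------------------------------------------
# Minimal web layer (single-page gallery on the stdlib HTTP server)
# --------------------------------------------------------------------------

_PAGE = """<!doctype html><html><head><meta charset="utf-8">
<title>neuroqc review</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
img {{ max-width: 95%; border: 1px solid #888; cursor: zoom-in; }}
img.zoom {{ max-width: none; }}
.badge {{ padding: 2px 8px; border-radius: 4px; color: white; margin: 2px; }}
.pass {{ background: #2a2; }} .fail {{ background: #c22; }}
</style></head><body>
<h2>{snapshot_id} <small>({index_1}/{total})</small></h2>
<p>{badges}</p>
<p><a href="{session_link}">open session</a></p>
<img src="/image/{snapshot_id}" onclick="this.classList.toggle('zoom')">
<form method="post" action="/score">
<input type="hidden" name="snapshot_id" value="{snapshot_id}">
<input type="hidden" name="index" value="{index}">
rater <input name="rater" value="{rater}">
score <select name="score">{options}</select>
comment <input name="comment" size="40" value="{comment}">
<button type="submit">save</button>
</form>
<p>
<a href="/?index={prev}&rater={rater}">&laquo; prev</a> |
<a href="/?index={next}&rater={rater}">next &raquo;</a> |
jump to next failed:
{jump_links}
</p></body></html>"""


def _render_page(gallery: Gallery, store: ReviewStore, index: int,
                 rater: str) -> str:
    entry = gallery[index]
    badges = "".join(
        f'<span class="badge {"pass" if ok else "fail"}">{html.escape(t)}'
        "</span>"
        for t, ok in entry.outcomes.items())
    current = store.current()
    comment, score = "", None
    if not current.empty:
        mine = current[(current.snapshot_id == entry.snapshot_id)
                       & (current.rater == rater)]
        if len(mine):
            comment = str(mine.iloc[-1]["comment"])
            score = int(mine.iloc[-1]["score"])
    options = "".join(
        f'<option value="{v}" {"selected" if v == score else ""}>'
        f"{v} ({label})</option>"
        for v, label in SCORE_LABELS.items())
    jump_links = " ".join(
        f'<a href="/jump?test={html.escape(t)}&index={index}&rater={rater}">'
        f"{html.escape(t)}</a>"
        for t in gallery.test_ids)
    return _PAGE.format(
        snapshot_id=html.escape(entry.snapshot_id), index=index,
        index_1=index + 1, total=len(gallery), badges=badges,
        session_link=html.escape(entry.session_link), rater=html.escape(rater),
        options=options, comment=html.escape(comment),
        prev=(index - 1) % len(gallery), next=(index + 1) % len(gallery),
        jump_links=jump_links)


def serve(snapshot_dir, manifest=None, scores="scores.tsv",
          port: int = 8080):  # pragma: no cover - interactive
    """Serve the review gallery on ``http://localhost:<port>``."""
    import urllib.parse
    from http.server import BaseHTTPRequestHandler, HTTPServer

    gallery = load_gallery(snapshot_dir, manifest)
    store = ReviewStore(scores)
    if not len(gallery):
        raise SystemExit(f"no snapshots found in {snapshot_dir}")

    class Handler(BaseHTTPRequestHandler):
        def _ok(self, body: bytes, ctype="text/html; charset=utf-8"):
            self.send_response(200)
            self.send_header("Content-Type", ctype)
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            url = urllib.parse.urlparse(self.path)
            qs = urllib.parse.parse_qs(url.query)
            index = int(qs.get("index", ["0"])[0]) % len(gallery)
            rater = qs.get("rater", ["anonymous"])[0]
            if url.path.startswith("/image/"):
                name = urllib.parse.unquote(url.path[len("/image/"):])
                for entry in gallery.entries:
                    if entry.snapshot_id == name:
                        ctype = ("image/gif" if name.endswith(".gif")
                                 else "image/png")
                        self._ok(entry.image_path.read_bytes(), ctype)
                        return
                self.send_error(404)
                return
            if url.path == "/jump":
                test_id = qs.get("test", [""])[0]
                index, _ = next_failed(gallery, test_id, index)
            self._ok(_render_page(gallery, store, index, rater).encode())

        def do_POST(self):
            length = int(self.headers.get("Content-Length", 0))
            form = urllib.parse.parse_qs(self.rfile.read(length).decode())
            index = int(form.get("index", ["0"])[0])
            rater = form.get("rater", ["anonymous"])[0]
            try:
                store.append(form["snapshot_id"][0], rater,
                             int(form.get("score", ["0"])[0]),
                             form.get("comment", [""])[0])
            except (ValueError, KeyError) as exc:
                self.send_error(400, str(exc))
                return
            self.send_response(303)
            self.send_header("Location", f"/?index={index}&rater={rater}")
            self.end_headers()

        def log_message(self, *args):
            pass

    server = HTTPServer(("", port), Handler)
    print(f"neuroqc review: serving {len(gallery)} snapshots "
          f"on http://localhost:{port}")
    server.serve_forever()
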