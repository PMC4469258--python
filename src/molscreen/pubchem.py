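"""Optional cross-linking with the PubChem Compound Database.

All network I/O in the package lives here, behind an injectable transport
(a callable ``url -> (status_code, body_text)``), so the whole test-suite
runs with networking disabled and a live client is a one-liner.  The wire
contract is the current PUG REST gateway.  Requests are rate-limited (the
public service asks for at most 5/s) and retried with jittered exponential
backoff.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import random
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Callable, Optional

from rdkit import Chem
from rdkit.Chem import inchi as _inchi

from .model import CompoundRecord

log = logging.getLogger("molscreen.pubchem")

__all__ = [
    "PubChemLink",
    "PubChemError",
    "PubChemOfflineError",
    "PubChemRemoteError",
    "PubChemResponseError",
    "PubChemClient",
]

BASE_URL = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"


class PubChemError(RuntimeError):
    pass


class PubChemOfflineError(PubChemError):
    """Raised immediately in offline mode; no network is attempted."""


class PubChemRemoteError(PubChemError):
    """Gateway unreachable or erroring after the configured retries."""


class PubChemResponseError(PubChemError):
    """Gateway answered, but the payload is missing an expected field."""


@dataclass(frozen=True)
class PubChemLink:
    compound_id: str
    cid: Optional[int]  # None <=> lookup returned no match
    query_key: str      # structure key used (standard InChIKey by default)
    retrieved: str      # ISO timestamp


def _default_transport(url: str, timeout: float = 15.0) -> tuple[int, str]:
    req = urllib.request.Request(url, headers={"User-Agent": "molscreen"})
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return resp.status, resp.read().decode()
    except urllib.error.HTTPError as exc:
        return exc.code, exc.read().decode(errors="replace")


class PubChemClient:
    """Gateway client with caching, retries and rate limiting.

    ``transport`` is any callable ``url -> (status, body)``; tests inject a
    mock.  ``connectivity_only=True`` keys identity lookups on the first
    (skeleton) block of the InChIKey instead of the full key.
    """

    def __init__(self, transport: Optional[Callable] = None,
                 offline: bool = False, max_retries: int = 3,
                 backoff: float = 0.5, rate_limit_per_s: float = 5.0,
                 connectivity_only: bool = False,
                 rng_seed: Optional[int] = None):
        self.transport = transport or _default_transport
        self.offline = offline
        self.max_retries = max_retries
        self.backoff = backoff
        self.min_interval = 1.0 / rate_limit_per_s if rate_limit_per_s else 0.0
        self.connectivity_only = connectivity_only
        self._cache: dict[str, object] = {}
        self._last_request = 0.0
        self._rng = random.Random(rng_seed)
        self.request_log: list[str] = []

    # -- plumbing ---------------------------------------------------------
    def _get_json(self, url: str) -> dict:
        if self.offline:
            raise PubChemOfflineError("client is in offline mode")
        last_exc: Optional[Exception] = None
        for attempt in range(self.max_retries):
            wait = self._last_request + self.min_interval - time.monotonic()
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            self.request_log.append(url)
            try:
                status, body = self.transport(url)
            except Exception as exc:  # timeouts, connection resets, ...
                last_exc = exc
                time.sleep(self.backoff * 2 ** attempt * (1 + self._rng.random()))
                continue
            if status == 404:
                return {}  # PUG REST answers 404 for "no hits"
            if status >= 400:
                last_exc = PubChemRemoteError(f"HTTP {status} from gateway")
                time.sleep(self.backoff * 2 ** attempt * (1 + self._rng.random()))
                continue
            try:
                return json.loads(body)
            except json.JSONDecodeError as exc:
                raise PubChemResponseError(f"gateway returned non-JSON body: {exc}")
        raise PubChemRemoteError(
            f"gateway unreachable after {self.max_retries} attempts: {last_exc}")

    def structure_key(self, record: CompoundRecord) -> str:
        key = _inchi.MolToInchiKey(record.mol)
        return key.split("-")[0] if self.connectivity_only else key

    # -- operations -------------------------------------------------------
    def lookup_identical(self, record: CompoundRecord) -> PubChemLink:
        """Exact-structure lookup by InChIKey; absent cid on no-match.
        Responses are cached by query key."""
        key = self.structure_key(record)
        cache_key = f"identity:{key}"
        if cache_key in self._cache:
            cid = self._cache[cache_key]
        else:
            url = f"{BASE_URL}/compound/inchikey/{urllib.parse.quote(key)}/cids/JSON"
            doc = self._get_json(url)
            cids = (doc.get("IdentifierList") or {}).get("CID") or []
            if doc and "IdentifierList" in doc and not isinstance(cids, list):
                raise PubChemResponseError("field 'IdentifierList.CID' is not a list")
            cid = int(cids[0]) if cids else None
            self._cache[cache_key] = cid
        return PubChemLink(
            compound_id=record.compound_id, cid=cid, query_key=key,
            retrieved=_dt.datetime.now(_dt.timezone.utc).isoformat())

    def remote_similarity_search(self, record: CompoundRecord,
                                 threshold: int = 90,
                                 max_hits: int = 100) -> list[int]:
        """2D-similarity search on the gateway; returns ranked CIDs
        truncated to ``max_hits``.  ``threshold`` is a percentage."""
        if not 0 < threshold <= 100:
            raise ValueError("threshold must be a percentage in (0, 100]")
        smiles = Chem.MolToSmiles(record.mol)
        cache_key = f"similarity:{smiles}:{threshold}"
        if cache_key not in self._cache:
            url = (f"{BASE_URL}/compound/fastsimilarity_2d/smiles/"
                   f"{urllib.parse.quote(smiles)}/cids/JSON"
                   f"?Threshold={threshold}")
            doc = self._get_json(url)
            if doc and "IdentifierList" not in doc:
                raise PubChemResponseError("response missing field 'IdentifierList'")
            cids = (doc.get("IdentifierList") or {}).get("CID") or []
            self._cache[cache_key] = [int(c) for c in cids]
        return list(self._cache[cache_key])[:max_hits]

    def link_table(self, links: list[PubChemLink]) -> str:
        """CSV export (compound_id, cid, query_key, retrieved)."""
        lines = ["compound_id,cid,query_key,retrieved"]
        for ln in links:
            cid = "" if ln.cid is None else str(ln.cid)
            lines.append(f"{ln.compound_id},{cid},{ln.query_key},{ln.retrieved}")
        return "\n".join(lines) + "\n"
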