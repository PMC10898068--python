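"""Quota-aware, cached entry fetching.

The upstream API allows a fixed number of requests per key per day (250 by
default), so large corpora are harvested over multiple days.  The client

* serves parsed entries from a directory cache of raw responses without
  touching the quota,
* persists the remaining daily budget in a small JSON sidecar keyed by UTC
  date, so interrupted runs resume where they left off, and
* raises :class:`QuotaExhaustedError` instead of issuing a request once the
  day's budget reaches zero.

The HTTP transport is injectable (any ``url -> bytes`` callable), which is
also how the test suite exercises the client offline.
"""

from __future__ import annotations

import datetime
import json
import urllib.error
import urllib.request
from pathlib import Path
from typing import Any, Callable

import yaml

from .models import OmimEntry
from .parse import OmimSchemaError, parse_entry

__all__ = [
    "OmimClient",
    "ClientConfig",
    "QuotaExhaustedError",
    "EntryNotFoundError",
    "MalformedResponseError",
    "InvalidMimError",
]

API_URL = "https://api.omim.org/api/entry?mimNumber={mim}&include=text,referenceList,geneMap&format=json&apiKey={key}"


class QuotaExhaustedError(RuntimeError):
    """The daily request budget is spent; retry after the UTC date rolls."""


class EntryNotFoundError(KeyError):
    pass


class MalformedResponseError(ValueError):
    pass


class InvalidMimError(ValueError):
    pass


class ClientConfig:
    """Configuration for :class:`OmimClient` (loadable from YAML)."""

    def __init__(self, api_key: str = "", cache_dir: str | Path = ".omim-cache",
                 daily_budget: int = 250):
        self.api_key = api_key
        self.cache_dir = Path(cache_dir)
        self.daily_budget = daily_budget

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClientConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            api_key=data.get("api_key", ""),
            cache_dir=data.get("cache_dir", ".omim-cache"),
            daily_budget=int(data.get("daily_budget", 250)),
        )


def _default_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            return resp.read()
    except urllib.error.HTTPError as exc:  # pragma: no cover - network path
        if exc.code == 404:
            raise EntryNotFoundError(url) from exc
        raise


class OmimClient:
    def __init__(
        self,
        config: ClientConfig,
        transport: Callable[[str], bytes] | None = None,
        today: Callable[[], datetime.date] | None = None,
    ):
        self.config = config
        self.transport = transport or _default_transport
        self._today = today or (lambda: datetime.datetime.now(datetime.timezone.utc).date())
        self.config.cache_dir.mkdir(parents=True, exist_ok=True)

    # -- quota ledger ------------------------------------------------------

    @property
    def _ledger_path(self) -> Path:
        return self.config.cache_dir / "quota.json"

    def remaining_budget(self) -> int:
        key = self._today().isoformat()
        if self._ledger_path.exists():
            ledger = json.loads(self._ledger_path.read_text())
        else:
            ledger = {}
        return int(ledger.get(key, self.config.daily_budget))

    def _spend(self) -> None:
        key = self._today().isoformat()
        ledger = (
            json.loads(self._ledger_path.read_text())
            if self._ledger_path.exists()
            else {}
        )
        ledger = {key: int(ledger.get(key, self.config.daily_budget)) - 1}
        self._ledger_path.write_text(json.dumps(ledger))

    # -- fetching ----------------------------------------------------------

    def _cache_path(self, mim_number: int) -> Path:
        return self.config.cache_dir / f"{mim_number}.json"

    def fetch_entry(self, mim_number: int) -> OmimEntry:
        """Return the parsed entry, from cache when available.

        Cache hits never consume quota; live fetches decrement the persisted
        daily budget and raise :class:`QuotaExhaustedError` when it is 0.
        """
        if not (isinstance(mim_number, int) and 100000 <= mim_number <= 999999):
            raise InvalidMimError(f"MIM number must be a 6-digit integer, got {mim_number!r}")

        cached = self._cache_path(mim_number)
        if cached.exists():
            raw = json.loads(cached.read_text())
            return self._parse(raw, mim_number)

        if self.remaining_budget() <= 0:
            raise QuotaExhaustedError(
                f"daily request budget exhausted for {self._today().isoformat()}"
            )
        payload = self.transport(
            API_URL.format(mim=mim_number, key=self.config.api_key)
        )
        try:
            raw = json.loads(payload)
        except json.JSONDecodeError as exc:
            raise MalformedResponseError(str(exc)) from exc
        entry = self._parse(raw, mim_number)  # validate before caching
        cached.write_text(json.dumps(raw, sort_keys=True))
        self._spend()
        return entry

    @staticmethod
    def _parse(raw: dict[str, Any], mim_number: int) -> OmimEntry:
        try:
            entry = parse_entry(raw)
        except OmimSchemaError as exc:
            raise MalformedResponseError(str(exc)) from exc
        if entry.mim_number != mim_number:
            raise EntryNotFoundError(
                f"requested {mim_number}, response carries {entry.mim_number}"
            )
        return entry
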