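"""Experiment level: an ordered collection of samples joined to a metadata table.

Each sample carries a unique identifier (UID); the experiment's metadata
table has exactly one row per sample, keyed by the ``uid`` column and kept
in the same order as the sample list. All experiment-level operations
(query, iterate, concat, region splitting, config assembly) preserve this
pairing.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, UidCollisionError
from .core import Sample, crop_sample

__all__ = ["Experiment", "mint_uid", "from_regions", "from_config"]


def mint_uid(rng: random.Random | None = None) -> str:
    """Random 128-bit identifier rendered as 32 hex digits.

    A seeded ``random.Random`` may be injected for reproducible fixtures.
    """
    r = rng if rng is not None else random.SystemRandom()
    return f"{r.getrandbits(128):032x}"


class Experiment:
    """Ordered samples + one metadata row per sample, joined on ``uid``."""

    def __init__(self, samples: list[Sample] | None = None, metadata: pd.DataFrame | None = None):
        self.samples: list[Sample] = list(samples or [])
        if metadata is None:
            metadata = pd.DataFrame({"uid": [s.uid for s in self.samples]})
        self.metadata = metadata.reset_index(drop=True)
        self._validate()

    def _validate(self):
        if "uid" not in self.metadata.columns:
            raise ValueError("metadata table must have a 'uid' column")
        if len(self.samples) != len(self.metadata):
            raise ValueError(
                f"{len(self.samples)} samples but {len(self.metadata)} metadata rows"
            )
        uids = [s.uid for s in self.samples]
        if len(set(uids)) != len(uids):
            dupes = {u for u in uids if uids.count(u) > 1}
            raise UidCollisionError(f"duplicate sample UIDs: {sorted(dupes)}")
        table_uids = self.metadata["uid"].tolist()
        if table_uids != uids:
            raise ValueError("metadata row order does not match sample order")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[tuple[pd.Series, Sample]]:
        """Yield (metadata_row, sample) pairs in stored order."""
        for (_, row), sample in zip(self.metadata.iterrows(), self.samples):
            yield row, sample

    def uids(self) -> list[str]:
        return [s.uid for s in self.samples]

    def add(self, sample: Sample, metadata_row: dict | pd.Series | None = None,
            uid_rng: random.Random | None = None) -> "Experiment":
        """Append a sample (and its metadata row) in place.

        A fresh UID is minted if the sample has none. Raises
        :class:`UidCollisionError` if the UID is already present.
        """
        if sample.uid is None:
            sample.uid = mint_uid(uid_rng)
        if sample.uid in set(self.uids()):
            raise UidCollisionError(f"UID {sample.uid!r} already present in experiment")
        row = dict(metadata_row or {})
        row["uid"] = sample.uid
        self.samples.append(sample)
        self.metadata = pd.concat(
            [self.metadata, pd.DataFrame([row])], ignore_index=True
        )
        # keep uid first for readability
        cols = ["uid"] + [c for c in self.metadata.columns if c != "uid"]
        self.metadata = self.metadata[cols]
        return self

    def query(self, predicate: Callable[[pd.Series], bool] | str) -> "Experiment":
        """Sub-experiment of rows satisfying *predicate*, order preserved.

        *predicate* is either a callable on metadata rows or a
        ``DataFrame.query`` expression string. Samples are shared (views),
        metadata rows are copied.
        """
        if isinstance(predicate, str):
            kept = self.metadata.query(predicate)
            idx = kept.index.to_list()
        else:
            idx = [i for i, (_, row) in enumerate(self.metadata.iterrows()) if predicate(row)]
        samples = [self.samples[i] for i in idx]
        meta = self.metadata.iloc[idx].reset_index(drop=True)
        return Experiment(samples, meta)

    @classmethod
    def concat(cls, experiments: Iterable["Experiment"]) -> "Experiment":
        """Concatenate experiments in order; metadata columns are unioned.

        Missing values in unioned columns are marked NA. A UID shared by
        two inputs raises :class:`UidCollisionError` naming the UID.
        """
        experiments = list(experiments)
        samples: list[Sample] = []
        seen: set[str] = set()
        for exp in experiments:
            for uid in exp.uids():
                if uid in seen:
                    raise UidCollisionError(f"UID {uid!r} appears in more than one experiment")
                seen.add(uid)
            samples.extend(exp.samples)
        if experiments:
            meta = pd.concat([e.metadata.copy() for e in experiments], ignore_index=True)
        else:
            meta = pd.DataFrame({"uid": []})
        return cls(samples, meta)


def from_regions(sample: Sample, region_set_name: str,
                 uid_rng: random.Random | None = None) -> Experiment:
    """Split one sample into an experiment, one cropped sample per region.

    Each region polygon of the named region set produces a sample cropped
    with ``shift_origin=True``; its metadata row records the parent UID,
    region name and region class, plus an ``empty`` flag for regions that
    retained no cells.
    """
    if region_set_name not in sample.regions:
        raise KeyError(f"unknown region set {region_set_name!r}")
    pset = sample.regions[region_set_name]
    exp = Experiment()
    if len(pset) == 0:
        import logging

        logging.getLogger(__name__).warning("region set %r is empty", region_set_name)
        return exp
    for entry in pset:
        sub = crop_sample(sample, entry.vertices, shift_origin=True)
        sub.uid = None
        exp.add(
            sub,
            {
                "parent_uid": sample.uid,
                "region": entry.name,
                "region_class": entry.class_label,
                "empty": sub.n_cells() == 0,
            },
            uid_rng=uid_rng,
        )
    return exp


def from_config(config_path: str | Path) -> Experiment:
    """Assemble an experiment from a CSV configuration file.

    The file must have a header with a ``path`` column naming project
    directories (relative paths resolve against the config file's
    directory); every other column becomes sample metadata. Rows are
    loaded in order.
    """
    from .io import load_project

    config_path = Path(config_path)
    cfg = pd.read_csv(config_path)
    if "path" not in cfg.columns:
        raise ConfigError(f"config {config_path} has no 'path' column")
    exp = Experiment()
    for i, row in cfg.iterrows():
        proj = Path(str(row["path"]))
        if not proj.is_absolute():
            proj = config_path.parent / proj
        try:
            sample = load_project(proj)
        except Exception as err:  # noqa: BLE001 - rewrap with row context
            raise ConfigError(f"config row {i}: cannot load project {proj}: {err}") from err
        meta = {c: row[c] for c in cfg.columns if c != "path"}
        meta["path"] = str(row["path"])
        if "uid" in meta:
            sample.uid = str(meta.pop("uid"))
        exp.add(sample, meta)
    return exp
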