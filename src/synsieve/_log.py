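"""Structured logging shared by all subcommands.

Every line has the form ``LEVEL<tab>operation<tab>message`` and goes to
stderr; :func:`attach_run_log` additionally mirrors it to a ``run.log``
file inside a run folder.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

_LOGGER_NAME = "synsieve"
_FORMAT = "%(levelname)s\t%(operation)s\t%(message)s"


class _DefaultOperation(logging.Filter):
    def filter(self, record: logging.LogRecord) -> bool:
        if not hasattr(record, "operation"):
            record.operation = "-"
        return True


def get_logger() -> logging.Logger:
    logger = logging.getLogger(_LOGGER_NAME)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_FORMAT))
        handler.addFilter(_DefaultOperation())
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def log(level: int, operation: str, message: str) -> None:
    get_logger().log(level, message, extra={"operation": operation})


def attach_run_log(out_dir: Path) -> logging.Handler:
    """Mirror log lines to ``<out_dir>/run.log``; returns the handler so the
    caller can detach it when the run finishes."""
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter(_FORMAT))
    handler.addFilter(_DefaultOperation())
    get_logger().addHandler(handler)
    return handler


def detach(handler: logging.Handler) -> None:
    get_logger().removeHandler(handler)
    handler.close()
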