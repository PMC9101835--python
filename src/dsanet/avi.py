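"""Minimal uncompressed AVI (RIFF) reader/writer for 8-bit grayscale video.

Angiography archives export AVI alongside PNG stacks; only the uncompressed
DIB flavour is supported here, which is enough for lossless round-trips
without any external codec.  Frames are stored as bottom-up 24-bit BGR DIBs
(the most widely readable uncompressed layout) with R=G=B.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]

_FOURCC_STREAM = b"00db"  # uncompressed DIB chunk of stream 0


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    if len(payload) % 2:
        payload += b"\x00"
    return fourcc + struct.pack("<I", len(payload)) + payload


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def _frame_to_dib(frame: np.ndarray) -> bytes:
    h, w = frame.shape
    row_bytes = (w * 3 + 3) // 4 * 4
    buf = np.zeros((h, row_bytes), dtype=np.uint8)
    bgr = np.repeat(frame[:, :, None], 3, axis=2)
    buf[:, : w * 3] = bgr.reshape(h, w * 3)
    return buf[::-1].tobytes()  # bottom-up


def _dib_to_frame(data: bytes, w: int, h: int) -> np.ndarray:
    row_bytes = (w * 3 + 3) // 4 * 4
    buf = np.frombuffer(data[: h * row_bytes], dtype=np.uint8).reshape(h, row_bytes)
    bgr = buf[::-1, : w * 3].reshape(h, w, 3)
    return bgr[:, :, 0].copy()


def write_avi(path, frames, fps: int = 4) -> None:
    """Write a stack of uint8 H×W frames as an uncompressed grayscale AVI."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to write")
    h, w = frames[0].shape
    for f in frames:
        if f.shape != (h, w):
            raise ValueError("all frames must share the same shape")
        if f.dtype != np.uint8:
            raise ValueError("frames must be uint8")
    n = len(frames)
    frame_size = ((w * 3 + 3) // 4 * 4) * h

    avih = _chunk(
        b"avih",
        struct.pack(
            "<14I",
            1_000_000 // fps,  # microseconds per frame
            frame_size * fps,  # max bytes per second
            0,
            0x10,  # AVIF_HASINDEX
            n,
            0,
            1,  # one stream
            frame_size,
            w,
            h,
            0, 0, 0, 0,
        ),
    )
    strh = _chunk(
        b"strh",
        b"vids" + b"DIB " + struct.pack("<10I4H", 0, 0, 0, 1, fps, 0, n,
                                        frame_size, 0xFFFFFFFF, 0, 0, 0, w, h),
    )
    strf = _chunk(
        b"strf",
        struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_size, 0, 0, 0, 0),
    )
    hdrl = _list(b"hdrl", avih + _list(b"strl", strh + strf))

    movi_payload = b""
    offsets = []
    for f in frames:
        offsets.append(len(movi_payload) + 4)
        movi_payload += _chunk(_FOURCC_STREAM, _frame_to_dib(f))
    movi = _list(b"movi", movi_payload)

    idx = b"".join(
        _FOURCC_STREAM + struct.pack("<III", 0x10, off, frame_size)
        for off in offsets
    )
    idx1 = _chunk(b"idx1", idx)

    riff_payload = b"AVI " + hdrl + movi + idx1
    Path(path).write_bytes(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def read_avi(path) -> np.ndarray:
    """Read an uncompressed grayscale AVI written by :func:`write_avi`.

    Returns a (T, H, W) uint8 array.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"not an AVI file: {path}")

    # main header is the first avih chunk
    pos = data.find(b"avih")
    if pos < 0:
        raise ValueError(f"missing avih header: {path}")
    fields = struct.unpack("<14I", data[pos + 8 : pos + 8 + 56])
    w, h = fields[8], fields[9]

    movi = data.find(b"movi")
    if movi < 0:
        raise ValueError(f"missing movi list: {path}")
    frames = []
    p = movi + 4
    while p + 8 <= len(data):
        fourcc = data[p : p + 4]
        (size,) = struct.unpack("<I", data[p + 4 : p + 8])
        if fourcc == b"idx1" or fourcc == b"LIST":
            break
        if fourcc == _FOURCC_STREAM:
            frames.append(_dib_to_frame(data[p + 8 : p + 8 + size], w, h))
        p += 8 + size + (size % 2)
    if not frames:
        raise ValueError(f"no video frames found: {path}")
    return np.stack(frames)
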