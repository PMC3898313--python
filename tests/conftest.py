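import os
import subprocess

import pytest

from shellforge import load_plugin_config


def oracle_env() -> dict:
    """Minimal deterministic environment shared by both execution routes."""
    return {"PATH": os.environ.get("PATH", "/usr/bin:/bin"), "LC_ALL": "C"}


def shell_oracle(line: str, env: dict | None = None, cwd: str | None = None):
    """Run one line through the system shell; returns (exit_code, stdout)."""
    proc = subprocess.run(
        ["bash", "-c", line],
        stdin=subprocess.DEVNULL,
        capture_output=True,
        env=env or oracle_env(),
        cwd=cwd,
    )
    return proc.returncode, proc.stdout.decode()


def plugin_xml(
    plugin_type: str = "aligner",
    plugin_id: str = "bwa_mem",
    extra_slots: str = "",
) -> str:
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<plugin id="{plugin_id}" type="{plugin_type}" version="1">
  <errorManagement policy="abort"/>
  <slots>
    <input name="READS" fileType="fastq"/>
    <output name="ALIGN" fileType="bam"/>
    <output name="COUNTS" fileType="tsv"/>{extra_slots}
  </slots>
  <env>
    <entry name="REF" value="hg19"/>
    <entry name="THREADS" value="4"/>
  </env>
  <sdk>
    <fetch>sdk fetch --slot {{slot}}</fetch>
    <push>sdk push --slot {{slot}}</push>
  </sdk>
</plugin>
"""


@pytest.fixture
def descriptor(tmp_path):
    path = tmp_path / "plugin.xml"
    path.write_text(plugin_xml())
    return load_plugin_config(path)


@pytest.fixture
def make_descriptor(tmp_path):
    def _make(plugin_type: str, plugin_id: str = "demo_plugin"):
        path = tmp_path / f"{plugin_type}.xml"
        path.write_text(plugin_xml(plugin_type, plugin_id))
        return load_plugin_config(path)

    return _make
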