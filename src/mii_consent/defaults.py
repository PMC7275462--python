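"""Bundled defaults: the synthetic broad-consent template (v1.6a
structure) and a registry pre-loaded with its policy-status codes."""

from __future__ import annotations

from importlib import resources

from .model import ConsentTemplate, load_template
from .registry import CodeRegistry

__all__ = ["default_template", "default_registry"]


def default_template() -> ConsentTemplate:
    """The bundled synthetic stand-in for the broad-consent template,
    version 1.6a: four sections, eight opt-in modules.  Statement texts
    are paraphrases, not the authoritative wording."""
    path = resources.files("mii_consent.data") / "template_v1_6a_synthetic.yaml"
    with resources.as_file(path) as p:
        return load_template(p)


def default_registry(template: ConsentTemplate | None = None) -> CodeRegistry:
    """A registry with the template's 24 policy-status codes allocated
    under the consent code system."""
    registry = CodeRegistry()
    registry.allocate_template(template or default_template())
    return registry
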