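"""CDS-Hooks service layer: discovery, prefetch resolution, and invocation.

The engine holds loaded content packs and an in-process patient store (a
map of patient id -> PatientBundle).  Prefetch templates are a closed FHIR
search dialect over that store (``patient``, ``code``, ``status``,
``_sort=date|-date``, ``_count``); completeness — every concept a rule needs
being reachable through at least one prefetch entry — is proven at startup,
not discovered per request.

``now`` is injectable so that rendered dates ({{Today + 2 weeks}}) are
reproducible; by default each invoke uses the current date.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import uuid as _uuid
from typing import Any, Optional
from urllib.parse import parse_qsl

from pydantic import BaseModel, field_validator

from .cards import RenderedCard, render_card, render_response
from .expressions import TruthValue, evaluate
from .fhir import PatientBundle, ResourceEnvelope, RESOURCE_TYPES, normalize_code
from .kb import ContentPack, PackError, ServiceDescriptor, rules_for_service

logger = logging.getLogger("cdspack.service")

_SUPPORTED_PARAMS = {"patient", "code", "status", "_sort", "_count"}
_PATIENT_TOKEN = "{{context.patientId}}"


class ServiceError(Exception):
    status = 500


class UnknownServiceError(ServiceError):
    status = 404


class BadRequestError(ServiceError):
    status = 400


class CdsRequest(BaseModel):
    hook: str
    hookInstance: str
    context: dict[str, Any]
    prefetch: Optional[dict[str, Any]] = None

    @field_validator("context")
    @classmethod
    def _patient_required(cls, v: dict) -> dict:
        if not v.get("patientId"):
            raise ValueError("context.patientId must be non-empty")
        return v


# ---------------------------------------------------------------------------
# Prefetch templates


class PrefetchQuery(BaseModel, frozen=True):
    resource_type: str
    codes: tuple[tuple[str, str], ...] = ()  # (system, code); empty = no filter
    status: Optional[str] = None
    sort_desc: Optional[bool] = None  # None = no sort requested
    count: Optional[int] = None


def parse_prefetch_template(template: str) -> PrefetchQuery:
    """Parse one FHIR search template; unsupported shapes fail at startup."""
    if "?" not in template:
        raise PackError(f"prefetch template has no query part: {template!r}")
    rtype, _, query = template.partition("?")
    if rtype not in RESOURCE_TYPES:
        raise PackError(f"prefetch template queries unsupported type {rtype!r}")
    codes: tuple[tuple[str, str], ...] = ()
    status = None
    sort_desc = None
    count = None
    saw_patient = False
    for key, value in parse_qsl(query, keep_blank_values=True):
        if key not in _SUPPORTED_PARAMS:
            raise PackError(f"unsupported search parameter {key!r} in {template!r}")
        if key == "patient":
            if value != _PATIENT_TOKEN:
                raise PackError(
                    f"patient parameter must be {_PATIENT_TOKEN}, got {value!r}"
                )
            saw_patient = True
        elif key == "code":
            parsed = []
            for tok in value.split(","):
                system, _, code = tok.rpartition("|")
                if not system or not code:
                    raise PackError(f"code filter must be 'system|code', got {tok!r}")
                parsed.append((system, normalize_code(code)))
            codes = tuple(parsed)
        elif key == "status":
            status = value
        elif key == "_sort":
            if value not in ("date", "-date"):
                raise PackError(f"_sort supports only date/-date, got {value!r}")
            sort_desc = value.startswith("-")
        elif key == "_count":
            count = int(value)
    if not saw_patient:
        raise PackError(f"prefetch template must filter by patient: {template!r}")
    return PrefetchQuery(
        resource_type=rtype, codes=codes, status=status, sort_desc=sort_desc, count=count
    )


def _run_query(query: PrefetchQuery, source: PatientBundle) -> list[ResourceEnvelope]:
    if query.resource_type == "Patient":
        return [source.patient]
    out = []
    for env in source.iter_type(query.resource_type):
        if query.status and env.attributes.get("status") != query.status:
            continue
        if query.codes:
            keys = {c.key() for c in env.codings()}
            if not keys & set(query.codes):
                continue
        out.append(env)
    if query.sort_desc is not None:
        out.sort(key=lambda e: (e.effective_time() or "", e.id), reverse=query.sort_desc)
    if query.count is not None:
        out = out[: query.count]
    return out


def resolve_prefetch(
    descriptor: ServiceDescriptor, source: PatientBundle
) -> dict[str, list[dict]]:
    """Evaluate every prefetch template against the bundle; empty hits are
    empty entries, never errors."""
    out: dict[str, list[dict]] = {}
    for name, template in descriptor.prefetch.items():
        query = parse_prefetch_template(template)
        out[name] = [env.to_json() for env in _run_query(query, source)]
    return out


def check_prefetch_completeness(pack: ContentPack) -> list[str]:
    """Prove every rule input concept of every service reachable via prefetch.

    A concept is reachable if some prefetch entry queries its resource type
    and either applies no code filter or includes one of the concept's
    codings.  Medication concepts are reachable through either medication
    resource type.
    """
    violations: list[str] = []
    for svc in pack.services:
        queries = [parse_prefetch_template(t) for t in svc.prefetch.values()]
        for rule in rules_for_service(pack, svc.service_id):
            for cid in rule.inputs:
                concept = pack.registry.resolve(cid)
                rtypes = {concept.resource_type}
                if concept.resource_type in ("MedicationStatement", "MedicationRequest"):
                    rtypes = {"MedicationStatement", "MedicationRequest"}
                keys = {c.key() for c in concept.codings}
                ok = any(
                    q.resource_type in rtypes
                    and (not q.codes or keys & set(q.codes))
                    for q in queries
                )
                if not ok:
                    violations.append(
                        f"service {svc.service_id}: concept [{cid}] of rule "
                        f"{rule.rule_id} not reachable via prefetch"
                    )
    return violations


# ---------------------------------------------------------------------------
# Engine


def _bundle_from_prefetch(patient_id: str, prefetch: dict[str, Any]) -> PatientBundle:
    """Rebuild an evaluation bundle from client-supplied prefetch resources."""
    patient = ResourceEnvelope(resource_type="Patient", id=patient_id, attributes={})
    seen: dict[str, ResourceEnvelope] = {}
    for entry in prefetch.values():
        resources = entry if isinstance(entry, list) else [entry]
        for obj in resources:
            if not isinstance(obj, dict) or "resourceType" not in obj:
                continue
            if obj["resourceType"] == "Patient":
                patient = ResourceEnvelope(
                    resource_type="Patient",
                    id=str(obj.get("id", patient_id)),
                    attributes={
                        k: v for k, v in obj.items() if k not in ("resourceType", "id")
                    },
                )
                continue
            env = ResourceEnvelope(
                resource_type=obj["resourceType"],
                id=str(obj.get("id", _uuid.uuid4())),
                attributes={k: v for k, v in obj.items() if k not in ("resourceType", "id")},
            )
            seen[f"{env.resource_type}/{env.id}"] = env
    return PatientBundle(patient=patient, resources=list(seen.values()))


class CdsEngine:
    """Holds loaded packs and a patient store; serves discovery and invoke."""

    def __init__(
        self,
        packs: list[ContentPack],
        patients: Optional[dict[str, PatientBundle]] = None,
        now: Optional[_dt.date] = None,
    ):
        self.packs = packs
        self.patients = patients or {}
        self.now = now
        self._services: dict[str, tuple[ContentPack, ServiceDescriptor]] = {}
        for pack in packs:
            for svc in pack.services:
                if svc.service_id in self._services:
                    raise PackError(f"duplicate service id {svc.service_id!r} across packs")
                self._services[svc.service_id] = (pack, svc)
        problems = [v for pack in packs for v in check_prefetch_completeness(pack)]
        if problems:
            raise PackError("prefetch completeness: " + "; ".join(problems))

    # -- CDS-Hooks endpoints -------------------------------------------------

    def discovery(self) -> dict[str, Any]:
        services = []
        for sid in sorted(self._services):
            _, svc = self._services[sid]
            services.append(
                {
                    "id": svc.service_id,
                    "hook": svc.hook,
                    "title": svc.title,
                    "description": svc.description or svc.title,
                    "prefetch": dict(svc.prefetch),
                }
            )
        return {"services": services}

    def invoke(
        self,
        service_id: str,
        request: CdsRequest,
        source: Optional[PatientBundle] = None,
        now: Optional[_dt.date] = None,
    ) -> dict[str, Any]:
        """Evaluate a service's rules and render cards for those that hold.

        Client-supplied prefetch overrides server-side resolution.  Cards
        fire only on a definite ``true``; response order follows rule
        declaration order, deduplicated by card id.
        """
        if service_id not in self._services:
            raise UnknownServiceError(f"no such service: {service_id!r}")
        pack, svc = self._services[service_id]
        if request.hook != svc.hook:
            raise BadRequestError(
                f"hook {request.hook!r} does not match service hook {svc.hook!r}"
            )
        patient_id = request.context["patientId"]
        if request.prefetch is not None:
            bundle = _bundle_from_prefetch(patient_id, request.prefetch)
        elif source is not None:
            bundle = source
        elif patient_id in self.patients:
            bundle = self.patients[patient_id]
        else:
            raise BadRequestError(f"no data source for patient {patient_id!r}")

        now = now or self.now or _dt.date.today()
        rendered: list[RenderedCard] = []
        emitted: set[str] = set()
        log: list[str] = []
        for rule in rules_for_service(pack, service_id):
            verdict = evaluate(rule.condition, bundle, pack.registry)
            log.append(f"{rule.rule_id}={verdict.value}")
            if verdict is not TruthValue.TRUE:
                continue
            for cid in rule.card_ids:
                if cid in emitted:
                    continue
                emitted.add(cid)
                rendered.append(render_card(pack.cards[cid], now=now))
        logger.info(
            "invoke service=%s patient=%s rules=[%s] cards=[%s]",
            service_id,
            patient_id,
            " ".join(log),
            " ".join(sorted(emitted)),
        )
        return render_response(rendered)

    def fired_cards(self, bundle: PatientBundle) -> set[str]:
        """Card ids of every rule holding true for this bundle, pack-wide."""
        fired: set[str] = set()
        for pack, svc in self._services.values():
            for rule in rules_for_service(pack, svc.service_id):
                if evaluate(rule.condition, bundle, pack.registry) is TruthValue.TRUE:
                    fired.update(rule.card_ids)
        return fired

    def invoke_all(
        self, bundle: PatientBundle, now: Optional[_dt.date] = None
    ) -> dict[str, dict[str, Any]]:
        """Invoke every registered service against one bundle (offline use)."""
        out = {}
        for sid in sorted(self._services):
            _, svc = self._services[sid]
            request = CdsRequest(
                hook=svc.hook,
                hookInstance=str(_uuid.uuid4()),
                context={"patientId": bundle.patient.id},
            )
            out[sid] = self.invoke(sid, request, source=bundle, now=now)
        return out


# ---------------------------------------------------------------------------
# WSGI application (stdlib HTTP layer; `serve` wraps it in wsgiref)


def make_wsgi_app(engine: CdsEngine):
    """A minimal WSGI app: GET /cds-services, POST /cds-services/{id}."""

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "")

        def respond(status: str, payload: dict):
            body = json.dumps(payload, ensure_ascii=False).encode("utf-8")
            start_response(
                status,
                [
                    ("Content-Type", "application/json; charset=utf-8"),
                    ("Content-Length", str(len(body))),
                ],
            )
            return [body]

        if method == "GET" and path == "/cds-services":
            return respond("200 OK", engine.discovery())
        if method == "POST" and path.startswith("/cds-services/"):
            service_id = path[len("/cds-services/") :]
            try:
                size = int(environ.get("CONTENT_LENGTH") or 0)
                raw = environ["wsgi.input"].read(size)
                request = CdsRequest(**json.loads(raw))
                now = None
                header_now = environ.get("HTTP_X_CDS_NOW")
                if header_now:
                    now = _dt.date.fromisoformat(header_now)
                return respond("200 OK", engine.invoke(service_id, request, now=now))
            except UnknownServiceError as e:
                return respond("404 Not Found", {"error": str(e)})
            except (BadRequestError, ValueError, KeyError) as e:
                return respond("400 Bad Request", {"error": str(e)})
        return respond("404 Not Found", {"error": f"no route for {method} {path}"})

    return app
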