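import datetime
import io
import json
import uuid

import pytest

from cdspack.conformance import validate_discovery, validate_response
from cdspack.fhir import serialize_bundle
from cdspack.kb import PackError
from cdspack.service import (
    BadRequestError,
    CdsRequest,
    UnknownServiceError,
    check_prefetch_completeness,
    make_wsgi_app,
    parse_prefetch_template,
    resolve_prefetch,
)
from cdspack.synth import bp_bundle, generate_scenario

NOW = datetime.date(2024, 3, 1)


def _request(hook="patient-view", patient="pt-x", prefetch=None):
    return CdsRequest(
        hook=hook, hookInstance=str(uuid.uuid4()),
        context={"patientId": patient}, prefetch=prefetch,
    )


class TestPrefetchTemplates:
    def test_supported_template_parses(self):
        q = parse_prefetch_template(
            "Observation?patient={{context.patientId}}"
            "&code=http://loinc.org|85354-9&_sort=-date&_count=1"
        )
        assert q.resource_type == "Observation"
        assert q.codes == (("http://loinc.org", "85354-9"),)
        assert q.sort_desc is True and q.count == 1

    def test_unsupported_parameter_fails_at_startup(self):
        with pytest.raises(PackError, match="unsupported search parameter 'bar'"):
            parse_prefetch_template("Observation?patient={{context.patientId}}&bar=1")

    def test_unknown_resource_type_fails(self):
        with pytest.raises(PackError, match="Foo"):
            parse_prefetch_template("Foo?patient={{context.patientId}}")

    def test_newest_panel_only_with_count_one(self, pack):
        svc = pack.service("hypertension-diagnosis")
        bundle = generate_scenario("grade1-newly-presenting", 2)
        out = resolve_prefetch(svc, bundle)
        # two panels in the bundle; the BP entry is unsorted-complete,
        # the heart-rate entry empty
        assert len(out["bloodPressure"]) == 2
        assert out["heartRate"] == []

    def test_sorted_entry_returns_latest_first(self, pack):
        svc = pack.service("hypertension-diagnosis")
        bundle = generate_scenario("grade1-newly-presenting", 2)
        out = resolve_prefetch(svc, bundle)
        dates = [r["effectiveDateTime"] for r in out["bloodPressure"]]
        assert dates == sorted(dates, reverse=True)

    def test_shipped_pack_prefetch_complete(self, pack):
        assert check_prefetch_completeness(pack) == []


class TestDiscovery:
    def test_lists_one_service_per_populated_category(self, engine):
        doc = engine.discovery()
        ids = [s["id"] for s in doc["services"]]
        assert ids == sorted(ids)
        assert "hypertension-diagnosis" in ids
        assert "hypertension-goal-management" in ids
        assert len(ids) == 7

    def test_conforms_to_bundled_schema(self, engine):
        assert validate_discovery(engine.discovery()) == []


class TestInvoke:
    def test_resistant_scenario_returns_card_18(self, engine):
        bundle = generate_scenario("resistant-hypertension", 4)
        doc = engine.invoke(
            "hypertension-complication-referral",
            _request(patient=bundle.patient.id),
            source=bundle,
            now=NOW,
        )
        (card,) = doc["cards"]
        assert card["summary"] == "Management of resistant hypertension."
        (suggestion,) = card["suggestions"]
        actions = suggestion["actions"]
        assert len(actions) == 3
        activity, appointment, referral = (a["resource"] for a in actions)
        assert activity["code"]["coding"][0]["code"] == "85354-9"
        assert appointment["start"] == "2024-03-15"  # now + 2 weeks
        assert referral["performerType"]["coding"][0]["code"] == "175651000"

    def test_newly_presenting_gets_self_monitoring_guidance(self, engine):
        bundle = bp_bundle(150, 95)
        doc = engine.invoke(
            "hypertension-diagnosis", _request(patient="pt-bp"), source=bundle, now=NOW
        )
        (card,) = doc["cards"]
        kinds = [a["resource"]["resourceType"] for a in card["suggestions"][0]["actions"]]
        assert kinds == ["ServiceRequest", "Appointment"]

    def test_empty_bundle_yields_no_cards(self, engine):
        bundle = generate_scenario("normal-bp", 0)
        empty = bundle.model_copy(update={"resources": []})
        for sid in [s["id"] for s in engine.discovery()["services"]]:
            doc = engine.invoke(sid, _request(), source=empty, now=NOW)
            assert doc == {"cards": []}

    def test_client_prefetch_overrides_source(self, engine):
        bundle = generate_scenario("bradycardia", 1)
        prefetch = {"all": [r.to_json() for r in bundle.resources]}
        doc = engine.invoke(
            "hypertension-adverse-events",
            _request(patient="pt-bradycardia", prefetch=prefetch),
            source=None,
            now=NOW,
        )
        assert [c["indicator"] for c in doc["cards"]] == ["warning"]

    def test_unknown_service_raises_404_semantics(self, engine):
        with pytest.raises(UnknownServiceError):
            engine.invoke("nope", _request(), source=generate_scenario("normal-bp", 0))

    def test_hook_mismatch_rejected(self, engine):
        with pytest.raises(BadRequestError, match="hook"):
            engine.invoke(
                "hypertension-diagnosis",
                _request(hook="order-select"),
                source=generate_scenario("normal-bp", 0),
            )

    def test_all_invoke_responses_conform_to_schema(self, engine):
        for spec_name in ["grade2-confirmed", "resistant-hypertension", "hyperkalemia"]:
            bundle = generate_scenario(spec_name, 7)
            for sid, doc in engine.invoke_all(bundle, now=NOW).items():
                assert validate_response(doc) == [], (spec_name, sid)


class TestWsgiApp:
    def _call(self, app, method, path, body=None, headers=None):
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "wsgi.input": io.BytesIO(body or b""),
            "CONTENT_LENGTH": str(len(body or b"")),
        }
        environ.update(headers or {})
        status_headers = {}

        def start_response(status, headers):
            status_headers["status"] = status

        chunks = app(environ, start_response)
        return status_headers["status"], json.loads(b"".join(chunks))

    def test_discovery_route(self, engine):
        status, doc = self._call(make_wsgi_app(engine), "GET", "/cds-services")
        assert status == "200 OK" and len(doc["services"]) == 7

    def test_invoke_route_with_injected_now(self, engine):
        bundle = generate_scenario("resistant-hypertension", 3)
        engine.patients[bundle.patient.id] = bundle
        body = json.dumps(
            {
                "hook": "patient-view",
                "hookInstance": str(uuid.uuid4()),
                "context": {"patientId": bundle.patient.id},
            }
        ).encode()
        status, doc = self._call(
            make_wsgi_app(engine),
            "POST",
            "/cds-services/hypertension-complication-referral",
            body,
            {"HTTP_X_CDS_NOW": "2024-03-01"},
        )
        assert status == "200 OK"
        assert doc["cards"][0]["suggestions"][0]["actions"][1]["resource"]["start"] == "2024-03-15"

    def test_unknown_service_is_404(self, engine):
        body = json.dumps(
            {"hook": "patient-view", "hookInstance": "h", "context": {"patientId": "p"}}
        ).encode()
        status, _ = self._call(make_wsgi_app(engine), "POST", "/cds-services/nope", body)
        assert status == "404 Not Found"

    def test_malformed_body_is_400(self, engine):
        status, _ = self._call(
            make_wsgi_app(engine), "POST", "/cds-services/hypertension-diagnosis", b"{bad"
        )
        assert status == "400 Bad Request"
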