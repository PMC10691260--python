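# SciRAPnano in vitro tool, version 1.0 skeleton bank.
# The 1.0 criterion wordings were distributed as supplementary material and are
# not shipped here; this bank carries criterion ids and section labels only so
# that evaluations keyed against version 1.0 (the titanium-dioxide case study)
# can be loaded, validated and scored. Every entry is marked text-unavailable.
tool_name: SciRAPnano in vitro
version: "1.0-skeleton"
criteria:
  RQ:
    - {id: 1, section: Test item and controls, text_available: false}
    - {id: 2, section: Test item and controls, text_available: false}
    - {id: 3, section: Test item and controls, text_available: false}
    - {id: 4, section: Test item and controls, text_available: false}
    - {id: 5, section: Physicochemical properties of the test item, text_available: false}
    - {id: 6, section: Physicochemical properties of the test item, text_available: false}
    - {id: 7, section: Physicochemical properties of the test item, text_available: false}
    - {id: 8, section: Physicochemical properties of the test item, text_available: false}
    - {id: 9, section: Physicochemical properties of the test item, text_available: false}
    - {id: 10, section: Physicochemical properties of the test item, text_available: false}
    - {id: 11, section: Physicochemical properties of the test item, text_available: false}
    - {id: 12, section: Physicochemical properties of the test item, text_available: false}
    - {id: 13, section: Physicochemical properties of the test item, text_available: false}
    - {id: 14, section: Physicochemical properties of the test item, text_available: false}
    - {id: 15, section: Physicochemical properties of the test item, text_available: false}
    - {id: 16, section: Test System, text_available: false}
    - {id: 17, section: Test System, text_available: false}
    - {id: 18, section: Test System, text_available: false}
    - {id: 19, section: Test System, text_available: false}
    - {id: 20, section: Test System, text_available: false}
    - {id: 21, section: Test System, text_available: false}
    - {id: 22, section: Test System, text_available: false}
    - {id: 23, section: Administration of test compound, text_available: false}
    - {id: 24, section: Administration of test compound, text_available: false}
    - {id: 25, section: Administration of test compound, text_available: false}
    - {id: 26, section: Administration of test compound, text_available: false}
    - {id: 27, section: Data collection and analysis, text_available: false}
    - {id: 28, section: Data collection and analysis, text_available: false}
    - {id: 29, section: Data collection and analysis, text_available: false}
    - {id: 30, section: Data collection and analysis, text_available: false}
    - {id: 31, section: Data collection and analysis, text_available: false}
    - {id: 32, section: Funding and competing interests, text_available: false}
    - {id: 33, section: Funding and competing interests, text_available: false}
  MQ:
    - {id: 1, section: Test item and controls, text_available: false}
    - {id: 2, section: Test item and controls, text_available: false}
    - {id: 3, section: Test item and controls, text_available: false}
    - {id: 4, section: Test item and controls, text_available: false}
    - {id: 5, section: Test item and controls, text_available: false}
    - {id: 6, section: Test item and controls, text_available: false}
    - {id: 7, section: Test System, text_available: false}
    - {id: 8, section: Test System, text_available: false}
    - {id: 9, section: Administration of test compound, text_available: false}
    - {id: 10, section: Administration of test compound, text_available: false}
    - {id: 11, section: Administration of test compound, text_available: false}
    - {id: 12, section: Administration of test compound, text_available: false}
    - {id: 13, section: Data collection and analysis, text_available: false}
    - {id: 14, section: Data collection and analysis, text_available: false}
    - {id: 15, section: Data collection and analysis, text_available: false}
    - id: 16
      section: Data collection and analysis
      text_available: false
      guidance: >-
        Known 1.0 wording: NMs physicochemical properties characterization was adequately performed
        at least "as received", "as administered" and "after administration or in situ". This
        criterion has no stated successor in version 2.0 and is not mapped forward.
    - {id: 17, section: Data collection and analysis, text_available: false}
    - {id: 18, section: Data collection and analysis, text_available: false}
    - {id: 19, section: Data collection and analysis, text_available: false}
  REL:
    - {id: 1, section: Relevance items, text: The identity of the tested item}
    - {id: 2, section: Relevance items, text: The test system used}
    - {id: 3, section: Relevance items, text: The endpoint studied}
    - {id: 4, section: Relevance items, text: The concentration used}
registries: {}
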