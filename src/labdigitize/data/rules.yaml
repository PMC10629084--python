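# Rule-based baseline: per-category span patterns (Python regex), header
# keyword map, and the conflict-resolution priority (most specific first).
patterns:
  LabRefRange:
    # comparator symbols with numbers, e.g. "3.5-9.5", "<5.0", ">=10"
    - '^\s*[<>≤≥]\s*=?\s*\d+(\.\d+)?\s*$'
    - '\d+(\.\d+)?\s*[-~–]{1,2}\s*\d+(\.\d+)?'
  LabUnit:
    # combinations with "/", "%", or English characters
    - '/'
    - '%'
    - '^[A-Za-z][A-Za-z0-9^·μ/%.]*$'
  LabResult:
    # unsigned numbers (decimal point excepted), optional high/low marker
    - '^\d+(\.\d+)?\s*[↑↓+-]?$'
    # qualitative Chinese results
    - '^(阴性|阳性|弱阳性|正常|未检出|未见异常)$'
  LabName:
    # mainly Chinese characters
    - '[一-鿿]'

priority: [LabRefRange, LabUnit, LabResult, LabName]

header_keywords:
  name: [项目名称, 项目, 名称, item, name]
  result: [结果, 检验结果, result, value]
  unit: [单位, unit]
  range: [参考范围, 参考值, 参考区间, reference, ref.range, ref, range]
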