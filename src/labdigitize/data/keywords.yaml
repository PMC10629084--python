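# Header / endline keyword roles for table-region location, plus the
# line-normalization thresholds (fractions of the mean line length).
# Matching is case-insensitive substring matching on the line text.
keywords:
  name:
    - 项目名称
    - 项目
    - 名称
    - item
    - name
  result:
    - 结果
    - 检验结果
    - result
    - value
  unit:
    - 单位
    - unit
  range:
    - 参考范围
    - 参考值
    - 参考区间
    - reference
    - ref.range
    - ref
    - range
  endline:
    - 检验者
    - 审核者
    - 送检医生
    - 报告医师
    - 签名
    - 备注
    - 本结果仅对该标本负责
    - operator
    - reviewer
    - signature
    - "note:"

thresholds:
  short: 0.6
  max_merged: 1.25
  fragment: 0.3
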