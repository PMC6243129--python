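<Lems>
  <ComponentType name="izhikevichCell">
    <Parameter name="C" dimension="capacitance"/>
    <Parameter name="k" dimension="conductance_per_voltage"/>
    <Parameter name="vr" dimension="voltage"/>
    <Parameter name="vt" dimension="voltage"/>
    <Parameter name="vpeak" dimension="voltage"/>
    <Parameter name="c" dimension="voltage"/>
    <Parameter name="a" dimension="per_time"/>
    <Parameter name="b" dimension="conductance"/>
    <Parameter name="d" dimension="current"/>
    <Requirement name="iSyn" dimension="current"/>
    <Exposure name="v" variable="v"/>
    <Exposure name="u" variable="u"/>
    <EventPort name="spike" direction="out"/>
    <Dynamics>
      <StateVariable name="v" dimension="voltage"/>
      <StateVariable name="u" dimension="current"/>
      <TimeDerivative variable="v" value="(k * (v - vr) * (v - vt) - u + iSyn) / C"/>
      <TimeDerivative variable="u" value="a * (b * (v - vr) - u)"/>
      <OnStart>
        <StateAssignment variable="v" value="vr"/>
        <StateAssignment variable="u" value="0 * b * vr"/>
      </OnStart>
      <OnCondition test="v &gt;= vpeak">
        <StateAssignment variable="v" value="c"/>
        <StateAssignment variable="u" value="u + d"/>
        <EventOut port="spike"/>
      </OnCondition>
    </Dynamics>
  </ComponentType>
  <ComponentType name="constantCurrent">
    <Parameter name="amplitude" dimension="current"/>
    <Exposure name="i" variable="i"/>
    <Dynamics>
      <DerivedVariable name="i" value="amplitude"/>
    </Dynamics>
  </ComponentType>
  <Component id="chattering" type="izhikevichCell" C="50 pF" k="1.5 nS_per_mV" vr="-60 mV" vt="-40 mV" vpeak="25 mV" c="-40 mV" a="0.03 per_ms" b="1 nS" d="150 pA"/>
  <Component id="drive" type="constantCurrent" amplitude="0.3 nA"/>
  <NeuronModel root="chattering">
    <Link from="drive" exposure="i" to="chattering" requirement="iSyn"/>
  </NeuronModel>
</Lems>
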